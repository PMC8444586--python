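"""Per-time-point differential abundance between two cohorts.

For every feature at every shared time point, abundances are compared
between two sample groups with the two-tailed Wilcoxon rank-sum test;
p-values are Benjamini-Hochberg adjusted within one feature level at one
time point, and effect sizes are reported as the log10 ratio of group
median abundances (reference over comparison).  Temporal-pattern
classification, fold-change-expansion counting and 2x2 category
enrichment summarize the per-time-point results across the study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleMetadata
from .stats import bh_adjust, chi_square_enrichment, log_median_ratio, rank_sum_test

__all__ = [
    "CohortDifference",
    "CohortDifferenceResults",
    "compare_cohorts",
    "classify_patterns",
    "count_expansion",
    "category_enrichment",
]

RESULT_COLUMNS = [
    "feature_id",
    "level",
    "timepoint",
    "p_value",
    "q_value",
    "log10_median_ratio",
    "direction",
    "n_ref",
    "n_comp",
]


def compare_cohorts(
    table: FeatureTable,
    metadata: SampleMetadata,
    timepoint: float,
    group_col: str = "cohort",
    reference: str | None = None,
    comparison: str | None = None,
    q_threshold: float = 0.01,
    pseudocount: float = 1e-10,
) -> pd.DataFrame:
    """Test every feature for a group difference at one time point.

    The BH family is all features of the table's level at this time
    point.  Direction is ``up_in_ref``/``up_in_comp`` from the sign of
    the log ratio when q < ``q_threshold``, else ``ns``.
    """
    meta = metadata.data
    at_t = meta[meta["age_months"] == timepoint]
    groups = sorted(at_t[group_col].unique())
    if reference is None or comparison is None:
        if len(groups) != 2:
            raise ValueError(
                f"{group_col} has {len(groups)} levels at t={timepoint}; "
                "specify reference and comparison explicitly"
            )
        reference, comparison = (reference or groups[0]), (comparison or groups[1])
    ref_ids = [
        s
        for s in at_t.loc[at_t[group_col] == reference, "sample_id"]
        if s in table.data.columns
    ]
    comp_ids = [
        s
        for s in at_t.loc[at_t[group_col] == comparison, "sample_id"]
        if s in table.data.columns
    ]
    for name, ids in ((reference, ref_ids), (comparison, comp_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"group {name!r} has {len(ids)} samples at time point {timepoint}"
            )
    ref = table.data[ref_ids].to_numpy()
    comp = table.data[comp_ids].to_numpy()
    p = np.array(
        [rank_sum_test(ref[i], comp[i]) for i in range(table.shape[0])]
    )
    q = bh_adjust(p)
    lmr = np.array(
        [
            log_median_ratio(ref[i], comp[i], pseudocount)
            for i in range(table.shape[0])
        ]
    )
    direction = np.where(
        q < q_threshold, np.where(lmr > 0, "up_in_ref", "up_in_comp"), "ns"
    )
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "level": table.level,
            "timepoint": timepoint,
            "p_value": p,
            "q_value": q,
            "log10_median_ratio": lmr,
            "direction": direction,
            "n_ref": len(ref_ids),
            "n_comp": len(comp_ids),
        }
    )


def classify_patterns(results: pd.DataFrame) -> pd.DataFrame:
    """Per-feature temporal pattern of significant differences.

    ``results`` concatenates :func:`compare_cohorts` outputs over time
    points (one feature level, same feature universe everywhere).
    Returns one row per feature with a per-time-point label string
    (ref / comp / ns), a directional-consistency flag (no sign flips
    among significant time points), and an expansion flag (|log ratio|
    strictly larger at the last shared time point than at the first).
    """
    timepoints = sorted(results["timepoint"].unique())
    universe = None
    for t in timepoints:
        feats = set(results.loc[results["timepoint"] == t, "feature_id"])
        if universe is None:
            universe = feats
        elif feats != universe:
            raise ValueError("feature universe differs across time points")
    wide_dir = results.pivot(
        index="feature_id", columns="timepoint", values="direction"
    )[timepoints]
    wide_lmr = results.pivot(
        index="feature_id", columns="timepoint", values="log10_median_ratio"
    )[timepoints]
    label = wide_dir.replace({"up_in_ref": "ref", "up_in_comp": "comp"})
    rows = []
    for fid in wide_dir.index:
        labels = list(label.loc[fid])
        sig = [x for x in labels if x != "ns"]
        consistent = len(set(sig)) <= 1
        expansion = bool(
            abs(wide_lmr.loc[fid, timepoints[-1]])
            > abs(wide_lmr.loc[fid, timepoints[0]])
        )
        rows.append(
            {
                "feature_id": fid,
                "pattern": "|".join(labels),
                "ever_significant": bool(sig),
                "consistent": consistent,
                "expansion": expansion,
            }
        )
    return pd.DataFrame(rows)


def count_expansion(
    results_t1: pd.DataFrame,
    results_t2: pd.DataFrame,
    features=None,
) -> tuple[int, int]:
    """Count features whose |log10 median ratio| strictly grows t1 -> t2."""
    r1 = results_t1.set_index("feature_id")["log10_median_ratio"]
    r2 = results_t2.set_index("feature_id")["log10_median_ratio"]
    if features is None:
        features = list(r1.index)
    missing = [f for f in features if f not in r1.index or f not in r2.index]
    if missing:
        raise KeyError(f"features absent from one time point: {missing[:5]}")
    n_exp = int(sum(abs(r2[f]) > abs(r1[f]) for f in features))
    return n_exp, len(features)


def category_enrichment(
    significant_ref: set,
    significant_comp: set,
    category,
) -> tuple[float, float]:
    """Chi-squared enrichment of a category among one group's features.

    Builds the 2x2 table (ref/comp-associated) x (in/out of category)
    and applies Pearson's chi-squared test on 1 df.  ``category`` maps a
    feature id to a bool.
    """
    a_in = sum(bool(category(f)) for f in significant_ref)
    b_in = sum(bool(category(f)) for f in significant_comp)
    table = [
        [a_in, len(significant_ref) - a_in],
        [b_in, len(significant_comp) - b_in],
    ]
    return chi_square_enrichment(table)


class CohortDifference:
    """Model of per-time-point group differences in a feature table.

    Parameters
    ----------
    table : FeatureTable
        Module-, pathway- or KO-level abundances.
    metadata : SampleMetadata
    group_col : str
        Metadata column splitting samples into two groups (default the
        cohort label; may be a covariate flag such as ``breastfed``).
    reference, comparison : str, optional
        Group values; default the two sorted levels of ``group_col``.
    q_threshold : float
        BH significance threshold for direction calls.
    pseudocount : float
        Zero-median guard for the log ratio.
    """

    def __init__(
        self,
        table: FeatureTable,
        metadata: SampleMetadata,
        group_col: str = "cohort",
        reference: str | None = None,
        comparison: str | None = None,
        q_threshold: float = 0.01,
        pseudocount: float = 1e-10,
    ):
        self.table = table
        self.metadata = metadata
        self.group_col = group_col
        self.reference = reference
        self.comparison = comparison
        self.q_threshold = q_threshold
        self.pseudocount = pseudocount

    def fit(self, timepoints=None) -> "CohortDifferenceResults":
        """Run the per-time-point tests; defaults to all shared ages."""
        if timepoints is None:
            timepoints = self.metadata.timepoints
        frames = [
            compare_cohorts(
                self.table,
                self.metadata,
                t,
                group_col=self.group_col,
                reference=self.reference,
                comparison=self.comparison,
                q_threshold=self.q_threshold,
                pseudocount=self.pseudocount,
            )
            for t in timepoints
        ]
        results = pd.concat(frames, ignore_index=True)
        return CohortDifferenceResults(self, results)


class CohortDifferenceResults:
    """Fitted per-feature, per-time-point differential-abundance results."""

    def __init__(self, model: CohortDifference, results: pd.DataFrame):
        self.model = model
        self.results = results
        self.patterns = classify_patterns(results)

    def significant(self, timepoint=None) -> pd.DataFrame:
        sig = self.results[self.results["direction"] != "ns"]
        if timepoint is not None:
            sig = sig[sig["timepoint"] == timepoint]
        return sig.reset_index(drop=True)

    def expansion(self, t1: float, t2: float, consistent_only: bool = True):
        """Fold-change expansion count among features significant at both."""
        r1 = self.results[self.results["timepoint"] == t1]
        r2 = self.results[self.results["timepoint"] == t2]
        sig1 = set(r1.loc[r1["direction"] != "ns", "feature_id"])
        sig2 = set(r2.loc[r2["direction"] != "ns", "feature_id"])
        feats = sorted(sig1 & sig2)
        if consistent_only:
            keep = set(
                self.patterns.loc[self.patterns["consistent"], "feature_id"]
            )
            feats = [f for f in feats if f in keep]
        if not feats:
            return 0, 0
        return count_expansion(r1, r2, feats)

    def summary(self) -> str:
        lines = [
            "Cohort differential abundance "
            f"({self.model.group_col}; level={self.model.table.level}; "
            f"q<{self.model.q_threshold})",
            f"{'time':>6} {'tested':>7} {'sig':>5} {'up_ref':>7} {'up_comp':>8}",
        ]
        for t in sorted(self.results["timepoint"].unique()):
            sub = self.results[self.results["timepoint"] == t]
            sig = sub[sub["direction"] != "ns"]
            lines.append(
                f"{t:>6g} {len(sub):>7d} {len(sig):>5d} "
                f"{(sig['direction'] == 'up_in_ref').sum():>7d} "
                f"{(sig['direction'] == 'up_in_comp').sum():>8d}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def patterns_to_tsv(self, path) -> None:
        self.patterns.to_csv(path, sep="\t", index=False)
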