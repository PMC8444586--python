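"""Metagenomic age: replicate age regression, calibration, delay tests.

The procedure quantifies developmental delay of one cohort's gut
functional capacities relative to another's:

1. within the training cohort, samples are randomly subsampled so every
   time point contributes the same number, then split 70-30 per time
   point into training and testing sets;
2. a regularized random forest predicts host age (months) from the
   functional profile; held-out performance is the Pearson r between
   predicted and true test ages, with the t-test p on n-2 df;
3. a smoothing spline (3 effective df) of test predictions against true
   test age calibrates the model's expected prediction at each age;
4. the *relative metagenomic age* of an opposite-cohort sample is the
   model's prediction minus the spline value at the sample's true age —
   negative values mean the sample's functional profile looks younger
   than its age, i.e. delayed development;
5. steps 1-4 run for R replicate models (fresh subsample and split
   each); per replicate and time point, a two-tailed Wilcoxon
   signed-rank test asks whether median relative age differs from zero,
   and the headline summary is the fraction of replicates calling a
   significant delay (median < 0) or acceleration (median > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleMetadata
from .forest import RegularizedRandomForest
from .spline import SmoothingSpline
from .stats import bh_adjust, pearson_r_test, signed_rank_test

__all__ = [
    "SplitPlan",
    "AgeModelReplicate",
    "balance_subsample",
    "split_train_test",
    "train_age_regressor",
    "fit_calibration_spline",
    "relative_ages",
    "test_delay",
    "MetagenomicAge",
    "MetagenomicAgeResults",
    "run_replicate_protocol",
]

TRAIN_FRACTION = 0.7


@dataclass(frozen=True)
class SplitPlan:
    """Balanced per-time-point sample counts and the 70-30 floor split."""

    timepoints: tuple[float, ...]
    n_per_timepoint: int
    seed: int

    @property
    def train_per_timepoint(self) -> int:
        return int(np.floor(TRAIN_FRACTION * self.n_per_timepoint))

    @property
    def test_per_timepoint(self) -> int:
        return self.n_per_timepoint - self.train_per_timepoint

    @property
    def n_train(self) -> int:
        return self.train_per_timepoint * len(self.timepoints)

    @property
    def n_test(self) -> int:
        return self.test_per_timepoint * len(self.timepoints)


def balance_subsample(
    metadata: SampleMetadata,
    cohort: str,
    seed: int,
    n_per_timepoint: int | None = None,
) -> tuple[list[str], SplitPlan]:
    """Randomly subsample a cohort to equal counts per time point.

    ``n_per_timepoint`` defaults to the smallest per-time-point count;
    a time point with fewer candidates than requested is an error.
    """
    rng = np.random.default_rng(seed)
    timepoints = tuple(
        sorted(
            metadata.data.loc[metadata.data["cohort"] == cohort, "age_months"].unique()
        )
    )
    if not timepoints:
        raise ValueError(f"cohort {cohort!r} has no samples")
    available = {t: metadata.samples_at(cohort, t) for t in timepoints}
    n_t = n_per_timepoint or min(len(v) for v in available.values())
    chosen: list[str] = []
    for t in timepoints:
        pool = available[t]
        if len(pool) < n_t:
            raise ValueError(
                f"time point {t} has {len(pool)} samples in cohort {cohort!r}, "
                f"fewer than the requested {n_t}"
            )
        pick = rng.choice(len(pool), size=n_t, replace=False)
        chosen.extend(pool[i] for i in sorted(pick))
    return chosen, SplitPlan(timepoints, n_t, seed)


def split_train_test(
    balanced_ids: list[str],
    metadata: SampleMetadata,
    plan: SplitPlan,
    seed: int,
) -> tuple[list[str], list[str]]:
    """70-30 split with every time point equally represented.

    Per time point, floor(0.7 * n_t) samples train and the rest test, so
    23/time-point gives 16 train + 7 test and 29 gives 20 + 9.
    """
    rng = np.random.default_rng(seed)
    ages = metadata.ages_for(balanced_ids)
    train: list[str] = []
    test: list[str] = []
    for t in plan.timepoints:
        ids_t = [s for s, a in zip(balanced_ids, ages) if a == t]
        assert len(ids_t) == plan.n_per_timepoint
        pick = rng.permutation(len(ids_t))
        k = plan.train_per_timepoint
        train.extend(ids_t[i] for i in sorted(pick[:k]))
        test.extend(ids_t[i] for i in sorted(pick[k:]))
    return train, test


def train_age_regressor(
    X: np.ndarray,
    ages: np.ndarray,
    n_trees: int = 10_000,
    gamma: float = 0.8,
    min_node_size: int = 5,
    seed: int = 0,
) -> RegularizedRandomForest:
    """Fit the regularized random forest age model.

    Requires at least two distinct training ages.  A feature table with
    no variation trains (the forest predicts the mean age) but logs a
    warning.  Tree-averaged predictions always lie within the convex
    hull of training ages.
    """
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages in the training set")
    if np.all(X == X[0:1, :]):
        warnings.warn("feature table is constant; age model will be uninformative")
    return RegularizedRandomForest(
        n_trees=n_trees, gamma=gamma, min_node_size=min_node_size, seed=seed
    ).fit(X, ages)


def fit_calibration_spline(
    test_predictions: np.ndarray, test_ages: np.ndarray, df: float = 3.0
) -> SmoothingSpline:
    """Smoothing spline of test predictions as a function of true age."""
    return SmoothingSpline(df=df).fit(test_ages, test_predictions)


@dataclass
class AgeModelReplicate:
    """One trained replicate: model, partition, calibration, performance."""

    index: int
    cohort: str
    regressor: RegularizedRandomForest = field(repr=False)
    feature_ids: list[str] = field(repr=False)
    train_ids: list[str] = field(repr=False)
    test_ids: list[str] = field(repr=False)
    plan: SplitPlan
    r: float
    p: float
    spline: SmoothingSpline = field(repr=False)

    def predict(self, table: FeatureTable, sample_ids: list[str]) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in table.data.index]
        if missing:
            raise KeyError(
                f"table is missing {len(missing)} model features, "
                f"e.g. {missing[:5]}"
            )
        X = table.data.loc[self.feature_ids, sample_ids].to_numpy().T
        return self.regressor.predict(X)


def _fit_replicate(
    index: int,
    table: FeatureTable,
    metadata: SampleMetadata,
    cohort: str,
    seed: int,
    n_per_timepoint: int | None,
    n_trees: int,
    gamma: float,
    spline_df: float,
) -> AgeModelReplicate:
    rng = np.random.default_rng(seed)
    s_balance, s_split, s_forest = (int(v) for v in rng.integers(0, 2**31 - 1, 3))
    balanced, plan = balance_subsample(metadata, cohort, s_balance, n_per_timepoint)
    train_ids, test_ids = split_train_test(balanced, metadata, plan, s_split)
    feats = table.feature_ids
    X_train = table.data.loc[feats, train_ids].to_numpy().T
    y_train = metadata.ages_for(train_ids)
    forest = train_age_regressor(
        X_train, y_train, n_trees=n_trees, gamma=gamma, seed=s_forest
    )
    X_test = table.data.loc[feats, test_ids].to_numpy().T
    test_pred = forest.predict(X_test)
    test_ages = metadata.ages_for(test_ids)
    r, p = pearson_r_test(test_pred, test_ages)
    spline = fit_calibration_spline(test_pred, test_ages, df=spline_df)
    return AgeModelReplicate(
        index, cohort, forest, feats, train_ids, test_ids, plan, r, p, spline
    )


def relative_ages(
    replicates: list[AgeModelReplicate],
    table: FeatureTable,
    metadata: SampleMetadata,
    sample_ids: list[str],
) -> pd.DataFrame:
    """Relative metagenomic age of each sample under each replicate.

    relative age = model prediction - spline(true age); one estimate per
    sample per replicate.
    """
    true_ages = metadata.ages_for(sample_ids)
    frames = []
    for rep in replicates:
        pred = rep.predict(table, sample_ids)
        rel = pred - np.asarray(rep.spline(true_ages), dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "replicate": rep.index,
                    "trained_on": rep.cohort,
                    "true_age": true_ages,
                    "predicted_age": pred,
                    "relative_age": rel,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_delay(
    estimates: pd.DataFrame, timepoint: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-replicate signed-rank test of zero median relative age.

    Returns one row per replicate with the two-tailed p, the median
    relative age and the direction (delay if median < 0, acceleration
    if > 0).
    """
    at_t = estimates[estimates["true_age"] == timepoint]
    rows = []
    for rep, sub in at_t.groupby("replicate"):
        vals = sub["relative_age"].to_numpy()
        if vals.size < 5:
            raise ValueError(
                f"replicate {rep} has {vals.size} estimates at t={timepoint}; "
                "need at least 5"
            )
        p = signed_rank_test(vals)
        med = float(np.median(vals))
        rows.append(
            {
                "replicate": rep,
                "timepoint": timepoint,
                "n": vals.size,
                "median_relative_age": med,
                "p_value": p,
                "significant_delay": bool(p < alpha and med < 0),
                "significant_acceleration": bool(p < alpha and med > 0),
            }
        )
    return pd.DataFrame(rows)


test_delay.__test__ = False  # public API name; not a test-runner item


class MetagenomicAge:
    """Cross-cohort metagenomic-age model.

    Parameters
    ----------
    table : FeatureTable
        Functional profiles (modules, pathways, or both concatenated)
        for the samples of both cohorts.
    metadata : SampleMetadata
        Must label exactly two cohorts in its ``cohort`` column.
    n_replicates : int
        Replicate models per cohort (default 10).
    n_trees, gamma : forest hyperparameters (defaults 10,000 trees,
        guided-regularization penalty 0.8; gamma=1 is a plain forest).
    n_per_timepoint : int, optional
        Balanced per-time-point sample count; defaults to the smallest
        per-time-point count in each cohort.
    spline_df : float
        Effective df of the calibration spline.
    alpha : float
        Per-replicate significance level of the delay test.
    """

    def __init__(
        self,
        table: FeatureTable,
        metadata: SampleMetadata,
        n_replicates: int = 10,
        n_trees: int = 10_000,
        gamma: float = 0.8,
        n_per_timepoint: int | None = None,
        spline_df: float = 3.0,
        alpha: float = 0.05,
        feature_set: str | None = None,
    ):
        cohorts = metadata.cohorts
        if len(cohorts) != 2:
            raise ValueError(f"expected exactly 2 cohorts, found {cohorts}")
        in_table = set(table.sample_ids)
        missing = [s for s in metadata.sample_ids if s not in in_table]
        if missing:
            raise ValueError(f"samples missing from table: {missing[:5]}")
        self.table = table
        self.metadata = metadata
        self.cohorts = tuple(cohorts)
        self.n_replicates = int(n_replicates)
        self.n_trees = int(n_trees)
        self.gamma = float(gamma)
        self.n_per_timepoint = n_per_timepoint
        self.spline_df = float(spline_df)
        self.alpha = float(alpha)
        self.feature_set = feature_set or table.level

    @classmethod
    def from_cohort_tables(
        cls, table_a: FeatureTable, table_b: FeatureTable, metadata: SampleMetadata, **kw
    ) -> "MetagenomicAge":
        """Build from one table per cohort (same feature universe)."""
        if list(table_a.data.index) != list(table_b.data.index):
            raise ValueError("cohort tables must share an identical feature universe")
        merged = FeatureTable(
            pd.concat([table_a.data, table_b.data], axis=1),
            table_a.level,
            table_a.normalized,
        )
        return cls(merged, metadata, **kw)

    def fit(self, seed: int = 0) -> "MetagenomicAgeResults":
        """Train R replicates per cohort and compute cross-cohort ages."""
        rng = np.random.default_rng(seed)
        replicates: dict[str, list[AgeModelReplicate]] = {}
        for cohort in self.cohorts:
            reps = []
            for i in range(self.n_replicates):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                reps.append(
                    _fit_replicate(
                        i + 1,
                        self.table,
                        self.metadata,
                        cohort,
                        rep_seed,
                        self.n_per_timepoint,
                        self.n_trees,
                        self.gamma,
                        self.spline_df,
                    )
                )
            replicates[cohort] = reps

        estimates = {}
        for train_cohort, target_cohort in (
            (self.cohorts[0], self.cohorts[1]),
            (self.cohorts[1], self.cohorts[0]),
        ):
            md = self.metadata.data
            target_ids = list(md.loc[md["cohort"] == target_cohort, "sample_id"])
            estimates[target_cohort] = relative_ages(
                replicates[train_cohort], self.table, self.metadata, target_ids
            )
        return MetagenomicAgeResults(self, replicates, estimates, seed)


class MetagenomicAgeResults:
    """Fitted replicate models, relative ages and delay tests."""

    def __init__(
        self,
        model: MetagenomicAge,
        replicates: dict[str, list[AgeModelReplicate]],
        estimates: dict[str, pd.DataFrame],
        seed: int,
    ):
        self.model = model
        self.replicates = replicates
        #: cohort -> relative-age estimates of that cohort's samples,
        #: produced by models trained on the opposite cohort
        self.relative_age_estimates = estimates
        self.seed = seed
        self.performance = self._performance_frame()
        self.delay_tests = self._delay_frame()

    def _performance_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, reps in self.replicates.items():
            p = [rep.p for rep in reps]
            q = bh_adjust(p)
            for rep, qv in zip(reps, q):
                rows.append(
                    {
                        "cohort": cohort,
                        "feature_set": self.model.feature_set,
                        "replicate": rep.index,
                        "n_train": rep.plan.n_train,
                        "n_test": rep.plan.n_test,
                        "r": rep.r,
                        "p_value": rep.p,
                        "q_value": qv,
                    }
                )
        return pd.DataFrame(rows)

    def _delay_frame(self) -> pd.DataFrame:
        frames = []
        for cohort, est in self.relative_age_estimates.items():
            for t in sorted(est["true_age"].unique()):
                df = test_delay(est, t, alpha=self.model.alpha)
                df.insert(0, "cohort", cohort)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def delay_fraction(self, cohort: str, timepoint: float) -> tuple[float, float]:
        """(delay, acceleration) replicate fractions for a cohort/age."""
        sub = self.delay_tests[
            (self.delay_tests["cohort"] == cohort)
            & (self.delay_tests["timepoint"] == timepoint)
        ]
        n = len(sub)
        if n == 0:
            raise KeyError(f"no delay tests for cohort {cohort!r} at t={timepoint}")
        return (
            float(sub["significant_delay"].sum() / n),
            float(sub["significant_acceleration"].sum() / n),
        )

    def median_relative_age(self, cohort: str, timepoint: float) -> float:
        est = self.relative_age_estimates[cohort]
        vals = est.loc[est["true_age"] == timepoint, "relative_age"]
        return float(vals.median())

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Metagenomic age analysis (feature set: {m.feature_set}, "
            f"{m.n_replicates} replicates, {m.n_trees} trees, gamma={m.gamma})",
            "",
            "Within-cohort test performance (Pearson r, held-out):",
        ]
        for cohort in m.cohorts:
            rs = self.performance.loc[self.performance["cohort"] == cohort, "r"]
            qs = self.performance.loc[self.performance["cohort"] == cohort, "q_value"]
            lines.append(
                f"  {cohort}: r in [{rs.min():.3f}, {rs.max():.3f}], "
                f"median {rs.median():.3f}; all q<0.01: {bool((qs < 0.01).all())}"
            )
        lines += ["", "Cross-cohort relative metagenomic age (months):"]
        header = f"  {'cohort':>6} {'age':>5} {'median':>8} {'delay':>7} {'accel':>7}"
        lines.append(header)
        for cohort in m.cohorts:
            est = self.relative_age_estimates[cohort]
            for t in sorted(est["true_age"].unique()):
                d, a = self.delay_fraction(cohort, t)
                med = self.median_relative_age(cohort, t)
                nrep = m.n_replicates
                lines.append(
                    f"  {cohort:>6} {t:>5g} {med:>8.2f} "
                    f"{int(round(d * nrep)):>4d}/{nrep} {int(round(a * nrep)):>4d}/{nrep}"
                )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------
    def plot_performance(self, ax=None):
        """Boxplots of replicate test-set r per training cohort."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        data = [
            self.performance.loc[self.performance["cohort"] == c, "r"]
            for c in self.model.cohorts
        ]
        ax.boxplot(data, tick_labels=list(self.model.cohorts))
        ax.set_ylabel("Pearson r (held-out)")
        ax.set_xlabel("training cohort")
        ax.set_title(f"Age-model performance ({self.model.feature_set})")
        return ax

    def plot_relative_age_density(self, timepoint: float, ax=None):
        """Pooled relative-age densities per cohort at one time point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for cohort in self.model.cohorts:
            est = self.relative_age_estimates[cohort]
            vals = est.loc[est["true_age"] == timepoint, "relative_age"]
            ax.hist(vals, bins=30, density=True, alpha=0.5, label=f"cohort {cohort}")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("relative metagenomic age (months)")
        ax.set_ylabel("density")
        ax.legend()
        ax.set_title(f"Relative metagenomic age at month {timepoint:g}")
        return ax

    def to_tsvs(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.performance.to_csv(
            out / "age_performance.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.concat(self.relative_age_estimates.values(), ignore_index=True).to_csv(
            out / "relative_ages.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.delay_tests.to_csv(
            out / "delay_tests.tsv", sep="\t", index=False, float_format="%.10g"
        )


def run_replicate_protocol(
    tables: dict[str, FeatureTable],
    metadata: SampleMetadata,
    feature_sets=("module", "pathway", "both"),
    seed: int = 0,
    **model_kw,
) -> dict[str, MetagenomicAgeResults]:
    """Run the full protocol for each requested feature set.

    ``tables`` maps level names ("module", "pathway") to tables sharing
    the same samples; "both" concatenates the two feature universes.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, MetagenomicAgeResults] = {}
    for fs in feature_sets:
        if fs == "both":
            if not {"module", "pathway"} <= set(tables):
                raise KeyError("feature set 'both' needs module and pathway tables")
            data = pd.concat([tables["module"].data, tables["pathway"].data])
            table = FeatureTable(data, level="both", normalized=True)
        elif fs in tables:
            table = tables[fs]
        else:
            raise KeyError(f"no table for feature set {fs!r}")
        model = MetagenomicAge(table, metadata, feature_set=fs, **model_kw)
        out[fs] = model.fit(seed=int(rng.integers(0, 2**31 - 1)))
    return out
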