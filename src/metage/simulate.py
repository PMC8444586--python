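"""Synthetic two-cohort longitudinal functional profiles with known truth.

The generator emulates the kind of data produced by functional annotation
of infant fecal shotgun metagenomes: per-sample KO abundance profiles for
two cohorts ("A", the reference, and "B", the comparison cohort) sampled
at discrete ages.  Three feature classes are simulated:

* **trending** — abundance follows a monotone saturating (logistic) curve
  in age, mimicking functional capacities that develop over the first
  year of life;
* **cohort-shifted** — age-constant abundance multiplied by a cohort-B
  specific factor, a non-developmental disruption;
* **constant** — age- and cohort-independent background.

Cohort B's mean for every feature is evaluated at the *delayed* age
``max(t - delay_months, t_min)``, so a positive ``delay_months`` makes
cohort B's functional profile at age ``t`` look like cohort A's at age
``t - delay``.  Observed abundances are the means times multiplicative
log-normal noise.  A block of universal single-copy KOs with constant
unit mean is appended for normalization.

All outputs are deterministic functions of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable, SampleMetadata

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_profiles",
    "generate_hierarchy",
    "generate_hit_table",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-cohort longitudinal generator.

    Defaults mirror the study design this package targets: 25 subjects
    per cohort sampled at months 2, 4, 6, 9 and 12, a 2-month
    developmental delay in cohort B, and log-normal noise with sigma 0.3
    on the log scale.
    """

    n_subjects_per_cohort: int = 25
    timepoints: tuple[float, ...] = (2.0, 4.0, 6.0, 9.0, 12.0)
    n_features_ko: int = 150
    n_universal_kos: int = 20
    delay_months: float = 2.0
    frac_trending: float = 0.5
    frac_cohort_shifted: float = 0.1
    noise_sd_log: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 2 or not np.all(np.isfinite(tp)):
            raise ValueError("timepoints must be >= 2 finite ages")
        if not np.all(np.diff(tp) > 0) or tp[0] <= 0:
            raise ValueError("timepoints must be strictly increasing and positive")
        for name in ("delay_months", "frac_trending", "frac_cohort_shifted", "noise_sd_log"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.n_subjects_per_cohort < 1 or self.n_features_ko < 1:
            raise ValueError("counts must be positive")
        if self.delay_months < 0:
            raise ValueError("delay_months must be >= 0")
        if not (0 <= self.frac_trending <= 1 and 0 <= self.frac_cohort_shifted <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_trending + self.frac_cohort_shifted > 1:
            raise ValueError("frac_trending + frac_cohort_shifted must be <= 1")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")


@dataclass
class GroundTruth:
    """Per-feature generative parameters, for oracle comparisons."""

    params: pd.DataFrame = field(repr=False)  # indexed by feature id
    delay_months: float = 0.0

    def __post_init__(self) -> None:
        if not self.params.index.is_unique:
            raise ValueError("each feature must appear exactly once")

    def expected_mean(self, feature_id: str, age: float, cohort: str) -> float:
        """Noise-free mean abundance of a feature at an age in a cohort."""
        row = self.params.loc[feature_id]
        t = age
        if cohort == "B":
            t = max(age - self.delay_months, self.t_min)
        mean = _logistic_mean(
            t, row["baseline"], row["amplitude"], row["midpoint"], row["rate"]
        )
        if cohort == "B":
            mean *= row["shift_multiplier"]
        return float(mean)

    @property
    def t_min(self) -> float:
        return float(self.params.attrs.get("t_min", 0.0))

    def to_tsv(self, path) -> None:
        out = self.params.copy()
        out.insert(0, "delay_months", self.delay_months)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _logistic_mean(t, baseline, amplitude, midpoint, rate):
    return baseline + amplitude / (1.0 + np.exp(-(t - midpoint) / rate))


def _feature_ids(n: int) -> list[str]:
    return [f"K{i:05d}" for i in range(1, n + 1)]


def generate_profiles(
    config: SyntheticConfig,
) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """Generate a KO-level abundance table for two longitudinal cohorts.

    Returns one sample per subject per time point in each cohort.  The
    universal single-copy KOs occupy the last ``n_universal_kos`` rows
    and are flagged with role ``universal`` in the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    tp = np.asarray(config.timepoints, dtype=float)
    t_min = tp[0]

    n_ko = config.n_features_ko
    n_uni = config.n_universal_kos
    n_total = n_ko + n_uni
    ids = _feature_ids(n_total)

    n_trend = int(round(config.frac_trending * n_ko))
    n_shift = int(round(config.frac_cohort_shifted * n_ko))
    n_shift = min(n_shift, n_ko - n_trend)
    roles = (
        ["trending"] * n_trend
        + ["shifted"] * n_shift
        + ["constant"] * (n_ko - n_trend - n_shift)
        + ["universal"] * n_uni
    )
    perm = rng.permutation(n_ko)  # shuffle roles among non-universal features
    roles = [roles[:n_ko][i] for i in perm] + roles[n_ko:]

    baseline = rng.lognormal(mean=0.0, sigma=0.5, size=n_total)
    amplitude = np.zeros(n_total)
    midpoint = np.zeros(n_total)
    rate = np.ones(n_total)
    shift_mult = np.ones(n_total)
    for i, role in enumerate(roles):
        if role == "universal":
            baseline[i] = 1.0
        elif role == "trending":
            midpoint[i] = rng.uniform(tp[0], tp[-1])
            rate[i] = rng.uniform(1.0, 3.0)
            if rng.random() < 0.5:  # increasing
                amplitude[i] = baseline[i] * rng.uniform(1.0, 3.0)
            else:  # decreasing, bounded to keep abundances positive
                amplitude[i] = -baseline[i] * rng.uniform(0.4, 0.8)
        elif role == "shifted":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shift_mult[i] = float(np.exp(sign * rng.uniform(np.log(1.5), np.log(3.0))))

    params = pd.DataFrame(
        {
            "role": roles,
            "baseline": baseline,
            "amplitude": amplitude,
            "midpoint": midpoint,
            "rate": rate,
            "shift_multiplier": shift_mult,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    params.attrs["t_min"] = float(t_min)
    truth = GroundTruth(params=params, delay_months=config.delay_months)

    rows = []
    sample_ids: list[str] = []
    matrix = []
    for cohort in ("A", "B"):
        for subj in range(1, config.n_subjects_per_cohort + 1):
            subject_id = f"{cohort}_S{subj:03d}"
            breastfed_subject = rng.random() < 0.6
            abx_prior = False
            for t in tp:
                sample_id = f"{subject_id}_m{t:g}"
                eff_t = max(t - config.delay_months, t_min) if cohort == "B" else t
                means = _logistic_mean(eff_t, baseline, amplitude, midpoint, rate)
                if cohort == "B":
                    means = means * shift_mult
                noise = np.exp(rng.normal(0.0, config.noise_sd_log, size=n_total))
                matrix.append(means * noise)
                sample_ids.append(sample_id)
                # covariate flags are realistic plumbing; they do not
                # influence abundances in this generator
                breastfed = breastfed_subject and t <= 9
                abx_now = rng.random() < 0.1
                rows.append(
                    {
                        "sample_id": sample_id,
                        "subject_id": subject_id,
                        "age_months": float(t),
                        "cohort": cohort,
                        "breastfed": int(breastfed),
                        "formula_fed": int(not breastfed),
                        "abx_current": int(abx_now),
                        "abx_prior": int(abx_prior),
                    }
                )
                abx_prior = abx_prior or abx_now

    table = FeatureTable(
        pd.DataFrame(np.column_stack(matrix), index=ids, columns=sample_ids),
        level="ko",
    )
    meta = SampleMetadata(pd.DataFrame(rows))
    return table, meta, truth


def universal_ko_ids(config: SyntheticConfig) -> list[str]:
    """Ids of the universal single-copy KO block."""
    n_total = config.n_features_ko + config.n_universal_kos
    return _feature_ids(n_total)[config.n_features_ko :]


def generate_hierarchy(
    config: SyntheticConfig,
    kos_per_module: int = 5,
    modules_per_pathway: int = 4,
    frac_multi_module: float = 0.15,
    seed_offset: int = 1,
):
    """Build a KEGG-style KO -> module -> pathway membership map.

    Non-universal KOs are partitioned into modules of ``kos_per_module``;
    a fraction of KOs additionally joins a second module so that
    support-based aggregation has genuine multi-membership to resolve.
    Pathways union the KO sets of ``modules_per_pathway`` consecutive
    modules.  Returns a :class:`~metage.profiling.FunctionalHierarchy`.
    """
    from .profiling import FunctionalHierarchy

    rng = np.random.default_rng(config.seed + seed_offset)
    kos = _feature_ids(config.n_features_ko)
    n_modules = max(2, config.n_features_ko // kos_per_module)
    ko_to_modules: dict[str, set[str]] = {k: set() for k in kos}
    module_ids = [f"M{i:05d}" for i in range(1, n_modules + 1)]
    for i, ko in enumerate(kos):
        ko_to_modules[ko].add(module_ids[i % n_modules])
    extra = rng.choice(len(kos), size=int(frac_multi_module * len(kos)), replace=False)
    for i in sorted(extra):
        current = next(iter(ko_to_modules[kos[i]]))
        other = module_ids[int(rng.integers(n_modules))]
        if other != current:
            ko_to_modules[kos[i]].add(other)

    n_pathways = max(1, n_modules // modules_per_pathway)
    pathway_ids = [f"map{i:05d}" for i in range(1, n_pathways + 1)]
    module_to_pathway = {
        m: pathway_ids[i // modules_per_pathway % n_pathways]
        for i, m in enumerate(module_ids)
    }
    ko_to_pathways = {
        ko: {module_to_pathway[m] for m in mods} for ko, mods in ko_to_modules.items()
    }
    return FunctionalHierarchy.from_memberships(ko_to_modules, ko_to_pathways)


def generate_hit_table(
    config: SyntheticConfig,
    n_reads: int = 1000,
    max_tied_genes: int = 3,
    max_kos_per_gene: int = 3,
    frac_unannotated_genes: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Emulate a best-hit read alignment table for one sample.

    Every read hits 1..``max_tied_genes`` genes tied at the best score;
    each gene carries 0..``max_kos_per_gene`` KO annotations.  Returns

    * ``hits`` — DataFrame (read_id, gene_id, score), one row per tied hit,
    * ``gene_ko_map`` — DataFrame (gene_id, ko_id), one row per pair,
    * ``expected_ko_counts`` — the exact fractional KO counts implied by
      even splitting of each read over its tied genes and of each gene's
      count over its KOs (the oracle for the profiling stage).
    """
    rng = np.random.default_rng(config.seed + 7)
    kos = _feature_ids(config.n_features_ko)
    n_genes = max(2 * config.n_features_ko, 10)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]

    gene_kos: dict[str, list[str]] = {}
    map_rows = []
    for g in genes:
        if rng.random() < frac_unannotated_genes:
            gene_kos[g] = []
            continue
        k = int(rng.integers(1, max_kos_per_gene + 1))
        chosen = list(rng.choice(kos, size=k, replace=False))
        gene_kos[g] = chosen
        map_rows.extend({"gene_id": g, "ko_id": ko} for ko in chosen)

    hit_rows = []
    gene_counts = dict.fromkeys(genes, 0.0)
    for r in range(n_reads):
        read_id = f"r{r + 1:06d}"
        k = int(rng.integers(1, max_tied_genes + 1))
        tied = rng.choice(n_genes, size=k, replace=False)
        score = float(rng.uniform(50, 300))
        for gi in tied:
            hit_rows.append({"read_id": read_id, "gene_id": genes[gi], "score": score})
            gene_counts[genes[gi]] += 1.0 / k

    expected = dict.fromkeys(kos, 0.0)
    for g, count in gene_counts.items():
        anns = gene_kos[g]
        if anns:
            for ko in anns:
                expected[ko] += count / len(anns)
    hits = pd.DataFrame(hit_rows)
    gene_ko_map = pd.DataFrame(map_rows)
    expected_counts = pd.Series(expected, name="expected_count")
    return hits, gene_ko_map, expected_counts
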