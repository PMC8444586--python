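"""Fractional-count functional profiling.

Turns best-hit read alignment tables into KO, module and pathway
abundance tables:

1. each read contributes total weight 1, split evenly over its tied
   best-hit genes;
2. each gene's count is split evenly over its KO annotations
   (unannotated mass is tallied, never silently dropped);
3. KO counts are scaled per sample by the median count of a set of
   universal single-copy KOs, so abundances approximate average copy
   number per cell;
4. KO abundances are aggregated to modules/pathways with support-based
   allocation: a KO belonging to several groups gives each group a share
   proportional to the group's *support* in that sample — the fraction
   of the group's member KOs detected (nonzero) there.

Every step conserves abundance mass exactly, up to the explicitly
reported annotation-loss and unmapped tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .containers import FeatureTable

__all__ = [
    "FunctionalHierarchy",
    "read_hit_table",
    "reads_to_gene_counts",
    "gene_counts_to_ko_counts",
    "normalize_single_copy",
    "aggregate_support",
    "profile_sample",
]


class UnnormalizableSampleError(ValueError):
    """Raised when a sample's universal single-copy KOs have zero median."""


@dataclass
class FunctionalHierarchy:
    """KO -> module and KO -> pathway membership maps, kept consistent."""

    ko_to_modules: dict[str, frozenset[str]] = field(repr=False)
    ko_to_pathways: dict[str, frozenset[str]] = field(repr=False)
    module_to_kos: dict[str, frozenset[str]] = field(repr=False)
    pathway_to_kos: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        for fwd, rev, what in (
            (self.ko_to_modules, self.module_to_kos, "module"),
            (self.ko_to_pathways, self.pathway_to_kos, "pathway"),
        ):
            for ko, groups in fwd.items():
                for g in groups:
                    if ko not in rev.get(g, frozenset()):
                        raise ValueError(
                            f"inconsistent hierarchy: {ko} lists {what} {g} "
                            f"but {g} does not list {ko}"
                        )
            for g, kos in rev.items():
                for ko in kos:
                    if g not in fwd.get(ko, frozenset()):
                        raise ValueError(
                            f"inconsistent hierarchy: {what} {g} lists {ko} "
                            f"but {ko} does not list {g}"
                        )

    @classmethod
    def from_memberships(cls, ko_to_modules, ko_to_pathways) -> "FunctionalHierarchy":
        ko_to_modules = {k: frozenset(v) for k, v in ko_to_modules.items()}
        ko_to_pathways = {k: frozenset(v) for k, v in ko_to_pathways.items()}
        module_to_kos: dict[str, set[str]] = {}
        for ko, mods in ko_to_modules.items():
            for m in mods:
                module_to_kos.setdefault(m, set()).add(ko)
        pathway_to_kos: dict[str, set[str]] = {}
        for ko, pws in ko_to_pathways.items():
            for p in pws:
                pathway_to_kos.setdefault(p, set()).add(ko)
        return cls(
            ko_to_modules,
            ko_to_pathways,
            {m: frozenset(v) for m, v in module_to_kos.items()},
            {p: frozenset(v) for p, v in pathway_to_kos.items()},
        )

    def groups(self, level: str) -> dict[str, frozenset[str]]:
        if level == "module":
            return self.module_to_kos
        if level == "pathway":
            return self.pathway_to_kos
        raise ValueError(f"level must be 'module' or 'pathway', got {level!r}")

    def memberships(self, level: str) -> dict[str, frozenset[str]]:
        return self.ko_to_modules if level == "module" else self.ko_to_pathways

    def to_tsv(self, path) -> None:
        rows = []
        for ko in sorted(self.ko_to_modules):
            for m in sorted(self.ko_to_modules[ko]):
                rows.append((ko, m, "module"))
        for ko in sorted(self.ko_to_pathways):
            for p in sorted(self.ko_to_pathways[ko]):
                rows.append((ko, p, "pathway"))
        pd.DataFrame(rows, columns=["ko_id", "group_id", "level"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "FunctionalHierarchy":
        df = pd.read_csv(path, sep="\t")
        required = {"ko_id", "group_id", "level"}
        if not required <= set(df.columns):
            raise ValueError(f"hierarchy TSV must have columns {sorted(required)}")
        k2m: dict[str, set[str]] = {}
        k2p: dict[str, set[str]] = {}
        for ko, group, level in df[["ko_id", "group_id", "level"]].itertuples(False):
            target = k2m if level == "module" else k2p
            target.setdefault(str(ko), set()).add(str(group))
        return cls.from_memberships(k2m, k2p)


def read_hit_table(path) -> pd.DataFrame:
    """Read a TSV of tied best-hit alignments (read_id, gene_id[, score])."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "gene_id": str})
    if not {"read_id", "gene_id"} <= set(df.columns):
        raise ValueError("hit table must have read_id and gene_id columns")
    return df


def reads_to_gene_counts(hits: pd.DataFrame) -> pd.Series:
    """Fractional gene counts: each read's unit weight split over its ties.

    A read matching k genes equally well contributes 1/k to each, so the
    total gene mass equals the number of distinct reads exactly.
    """
    if hits.empty:
        raise ValueError("hit table is empty")
    if hits[["read_id", "gene_id"]].isna().any().any():
        raise ValueError("hit table contains missing read or gene ids")
    if hits.duplicated(["read_id", "gene_id"]).any():
        raise ValueError("duplicate (read_id, gene_id) pairs in hit table")
    ties = hits.groupby("read_id")["gene_id"].transform("size")
    weights = 1.0 / ties
    counts = weights.groupby(hits["gene_id"]).sum()
    counts.name = "count"
    return counts.sort_index()


def gene_counts_to_ko_counts(
    gene_counts: pd.Series, gene_ko_map: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Split each gene's count evenly over its KO annotations.

    Returns the KO count vector and the annotation-loss tally: the total
    count carried by genes with no KO annotation.  Conservation holds
    exactly: ``ko_counts.sum() + loss == gene_counts.sum()``.
    """
    if not {"gene_id", "ko_id"} <= set(gene_ko_map.columns):
        raise ValueError("gene->KO map must have gene_id and ko_id columns")
    n_kos = gene_ko_map.groupby("gene_id")["ko_id"].size()
    annotated = gene_counts.index.intersection(n_kos.index)
    loss = float(gene_counts.drop(annotated).sum())
    if annotated.empty:
        return pd.Series(dtype=float, name="count"), loss
    share = gene_counts.loc[annotated] / n_kos.loc[annotated]
    merged = gene_ko_map[gene_ko_map["gene_id"].isin(annotated)].copy()
    merged["share"] = share.loc[merged["gene_id"]].to_numpy()
    ko_counts = merged.groupby("ko_id")["share"].sum()
    ko_counts.name = "count"
    return ko_counts.sort_index(), loss


def normalize_single_copy(
    table: FeatureTable, universal_kos: list[str]
) -> FeatureTable:
    """Scale each sample by the median count of universal single-copy KOs.

    After scaling, the median abundance of the universal KOs is 1 in
    every sample, so values approximate average gene copy number per
    cell.  A sample whose universal median is zero cannot be normalized
    and raises :class:`UnnormalizableSampleError` naming it.
    """
    if table.level != "ko":
        raise ValueError("single-copy normalization applies to KO-level tables")
    present = [k for k in universal_kos if k in table.data.index]
    if not present:
        raise ValueError("no universal KO present in the table")
    med = table.data.loc[present].median(axis=0)
    bad = med.index[med.to_numpy() <= 0].tolist()
    if bad:
        raise UnnormalizableSampleError(
            f"universal single-copy KO median is zero in samples: {bad[:5]}"
        )
    return FeatureTable(table.data.div(med, axis=1), level="ko", normalized=True)


def aggregate_support(
    table: FeatureTable, hierarchy: FunctionalHierarchy, level: str
) -> tuple[FeatureTable, pd.Series]:
    """Support-based aggregation of KO abundances to modules or pathways.

    For each sample, a group's support is the fraction of its member KOs
    detected (abundance > 0) in that sample.  A KO belonging to several
    groups splits its abundance across them proportionally to their
    supports (evenly if every candidate support is zero); a KO in one
    group gives it everything.  Per sample, group totals plus the
    unmapped tally (KOs absent from the hierarchy) equal the KO total.

    Returns the aggregated table and the per-sample unmapped tally.
    """
    groups = hierarchy.groups(level)
    memberships = hierarchy.memberships(level)
    group_ids = sorted(groups)
    g_index = {g: i for i, g in enumerate(group_ids)}
    kos = table.feature_ids
    abund = table.data.to_numpy(dtype=float)  # K x S
    n_samples = abund.shape[1]

    # membership matrix M (G x K) over KOs present in the table
    M = np.zeros((len(group_ids), len(kos)))
    mapped = np.zeros(len(kos), dtype=bool)
    for j, ko in enumerate(kos):
        for g in memberships.get(ko, ()):
            M[g_index[g], j] = 1.0
        mapped[j] = ko in memberships and len(memberships[ko]) > 0

    group_sizes = np.array([len(groups[g]) for g in group_ids], dtype=float)
    detected = (abund > 0).astype(float)  # K x S
    # support per group per sample: detected members / group size (group
    # size counts all member KOs, including ones absent from the table)
    support = (M @ detected) / group_sizes[:, None]  # G x S

    out = np.zeros((len(group_ids), n_samples))
    unmapped = np.zeros(n_samples)
    for s in range(n_samples):
        sup = support[:, s]
        denom = M.T @ sup  # per-KO sum of candidate supports
        n_groups_per_ko = M.sum(axis=0)
        for j in range(len(kos)):
            a = abund[j, s]
            if a == 0:
                continue
            if not mapped[j]:
                unmapped[s] += a
                continue
            cand = np.flatnonzero(M[:, j])
            if denom[j] > 0:
                shares = sup[cand] / denom[j]
            else:
                shares = np.full(cand.size, 1.0 / cand.size)
            out[cand, s] += a * shares
    agg = FeatureTable(
        pd.DataFrame(out, index=group_ids, columns=table.sample_ids),
        level=level,
        normalized=table.normalized,
    )
    return agg, pd.Series(unmapped, index=table.sample_ids, name="unmapped")


def profile_sample(
    hits: pd.DataFrame, gene_ko_map: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Convenience: hit table -> fractional KO counts + annotation loss."""
    gene_counts = reads_to_gene_counts(hits)
    return gene_counts_to_ko_counts(gene_counts, gene_ko_map)
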