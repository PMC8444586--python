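"""Pipeline orchestration: synthesize -> profile -> differential -> age.

A single YAML config drives the whole run; every stage writes plain TSV
outputs into the run directory and records its parameters, seeds and
output content hashes in ``manifest.json``.  Reruns with an unchanged
config reuse a stage's outputs when its recorded inputs are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .age import run_replicate_protocol
from .containers import FeatureTable, SampleMetadata, read_universal_kos
from .differential import CohortDifference
from .profiling import (
    FunctionalHierarchy,
    aggregate_support,
    normalize_single_copy,
)
from .simulate import (
    SyntheticConfig,
    generate_hierarchy,
    generate_profiles,
    universal_ko_ids,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("metage")

STAGES = ("simulate", "profile", "diff", "age")


@dataclass
class RunConfig:
    """Everything a reproducible run needs, YAML round-trippable."""

    outdir: str = "metage_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synthetic: dict = field(default_factory=dict)
    diff: dict = field(
        default_factory=lambda: {
            "levels": ["module", "pathway"],
            "q_threshold": 0.01,
            "pseudocount": 1e-10,
            "group_col": "cohort",
        }
    )
    age: dict = field(
        default_factory=lambda: {
            "feature_sets": ["module", "pathway", "both"],
            "n_replicates": 10,
            "n_trees": 10000,
            "gamma": 0.8,
            "spline_df": 3.0,
            "alpha": 0.05,
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def synthetic_config(self) -> SyntheticConfig:
        kw = dict(self.synthetic)
        kw.setdefault("seed", self.seed)
        if "timepoints" in kw:
            kw["timepoints"] = tuple(float(t) for t in kw["timepoints"])
        return SyntheticConfig(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _stage_fresh(manifest: dict, out: Path, stage: str, sig: str) -> bool:
    prior = manifest.get("stages", {}).get(stage)
    if not prior or prior.get("signature") != sig:
        return False
    for fname, digest in prior.get("outputs", {}).items():
        f = out / fname
        if not f.exists() or _sha256(f) != digest:
            return False
    return True


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.setdefault("stages", {})
    manifest["seed"] = config.seed
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(v) for s, v in zip(STAGES, rng.integers(0, 2**31 - 1, 4))}
    manifest["stage_seeds"] = stage_seeds

    def record(stage: str, sig: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "signature": sig,
            "seed": stage_seeds[stage],
            "outputs": {f.name: _sha256(f) for f in files},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if "simulate" in config.stages:
        sig = _config_hash({"synthetic": config.synthetic, "seed": stage_seeds["simulate"]})
        if force or not _stage_fresh(manifest, out, "simulate", sig):
            log.info("[simulate] generating synthetic profiles")
            scfg_kw = dict(config.synthetic)
            scfg_kw["seed"] = stage_seeds["simulate"]
            if "timepoints" in scfg_kw:
                scfg_kw["timepoints"] = tuple(float(t) for t in scfg_kw["timepoints"])
            scfg = SyntheticConfig(**scfg_kw)
            table, meta, truth = generate_profiles(scfg)
            hier = generate_hierarchy(scfg)
            table.to_tsv(out / "ko_table.tsv")
            meta.to_tsv(out / "metadata.tsv")
            truth.to_tsv(out / "ground_truth.tsv")
            hier.to_tsv(out / "hierarchy.tsv")
            (out / "universal_kos.txt").write_text(
                "\n".join(universal_ko_ids(scfg)) + "\n"
            )
            record(
                "simulate",
                sig,
                [
                    out / f
                    for f in (
                        "ko_table.tsv",
                        "metadata.tsv",
                        "ground_truth.tsv",
                        "hierarchy.tsv",
                        "universal_kos.txt",
                    )
                ],
            )
        else:
            log.info("[simulate] outputs up to date, skipping")

    if "profile" in config.stages:
        inputs = ["ko_table.tsv", "hierarchy.tsv", "universal_kos.txt"]
        for f in inputs:
            if not (out / f).exists():
                raise FileNotFoundError(f"[profile] missing input {out / f}")
        sig = _config_hash({"inputs": {f: _sha256(out / f) for f in inputs}})
        if force or not _stage_fresh(manifest, out, "profile", sig):
            log.info("[profile] normalizing and aggregating")
            table = FeatureTable.from_tsv(out / "ko_table.tsv", level="ko")
            hier = FunctionalHierarchy.from_tsv(out / "hierarchy.tsv")
            uni = read_universal_kos(out / "universal_kos.txt")
            norm = normalize_single_copy(table, uni)
            norm.to_tsv(out / "ko_normalized.tsv")
            files = [out / "ko_normalized.tsv"]
            tallies = {}
            for level in ("module", "pathway"):
                agg, unmapped = aggregate_support(norm, hier, level)
                agg.to_tsv(out / f"{level}_table.tsv")
                tallies[level] = unmapped
                files.append(out / f"{level}_table.tsv")
            pd.DataFrame(tallies).rename_axis("sample_id").to_csv(
                out / "unmapped_tallies.tsv", sep="\t", float_format="%.10g"
            )
            files.append(out / "unmapped_tallies.tsv")
            record("profile", sig, files)
        else:
            log.info("[profile] outputs up to date, skipping")

    if "diff" in config.stages:
        levels = list(config.diff.get("levels", ["module", "pathway"]))
        inputs = ["metadata.tsv"] + [f"{lv}_table.tsv" for lv in levels]
        for f in inputs:
            if not (out / f).exists():
                raise FileNotFoundError(f"[diff] missing input {out / f}")
        sig = _config_hash(
            {"diff": config.diff, "inputs": {f: _sha256(out / f) for f in inputs}}
        )
        if force or not _stage_fresh(manifest, out, "diff", sig):
            meta = SampleMetadata.from_tsv(out / "metadata.tsv")
            files = []
            for level in levels:
                log.info("[diff] per-time-point tests at %s level", level)
                table = FeatureTable.from_tsv(
                    out / f"{level}_table.tsv", level=level, normalized=True
                )
                res = CohortDifference(
                    table,
                    meta,
                    group_col=config.diff.get("group_col", "cohort"),
                    q_threshold=config.diff.get("q_threshold", 0.01),
                    pseudocount=config.diff.get("pseudocount", 1e-10),
                ).fit()
                res.to_tsv(out / f"diff_{level}.tsv")
                res.patterns_to_tsv(out / f"patterns_{level}.tsv")
                files += [out / f"diff_{level}.tsv", out / f"patterns_{level}.tsv"]
            record("diff", sig, files)
        else:
            log.info("[diff] outputs up to date, skipping")

    if "age" in config.stages:
        inputs = ["metadata.tsv", "module_table.tsv", "pathway_table.tsv"]
        for f in inputs:
            if not (out / f).exists():
                raise FileNotFoundError(f"[age] missing input {out / f}")
        sig = _config_hash(
            {
                "age": config.age,
                "seed": stage_seeds["age"],
                "inputs": {f: _sha256(out / f) for f in inputs},
            }
        )
        if force or not _stage_fresh(manifest, out, "age", sig):
            meta = SampleMetadata.from_tsv(out / "metadata.tsv")
            tables = {
                lv: FeatureTable.from_tsv(
                    out / f"{lv}_table.tsv", level=lv, normalized=True
                )
                for lv in ("module", "pathway")
            }
            kw = dict(config.age)
            feature_sets = kw.pop("feature_sets", ["module", "pathway", "both"])
            bundles = run_replicate_protocol(
                tables,
                meta,
                feature_sets=feature_sets,
                seed=stage_seeds["age"],
                **kw,
            )
            files = []
            for fs, res in bundles.items():
                log.info("[age] feature set %s done", fs)
                d = out / f"age_{fs}"
                res.to_tsvs(d)
                files += [
                    d / "age_performance.tsv",
                    d / "relative_ages.tsv",
                    d / "delay_tests.tsv",
                ]
            manifest["stages"]["age"] = {
                "signature": sig,
                "seed": stage_seeds["age"],
                "outputs": {
                    str(f.relative_to(out)): _sha256(f) for f in files
                },
            }
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        else:
            log.info("[age] outputs up to date, skipping")

    return manifest


def validate_inputs(
    table_paths: dict[str, str] | None = None,
    metadata_path: str | None = None,
) -> dict:
    """Schema and consistency checks; returns a structured report.

    Never mutates inputs.  The report maps check names to lists of
    findings; an all-empty report means a clean fixture.
    """
    report: dict[str, list[str]] = {"errors": [], "warnings": []}
    meta = None
    if metadata_path is not None:
        try:
            meta = SampleMetadata.from_tsv(metadata_path)
        except Exception as exc:  # surfaced, not raised: this is a report
            report["errors"].append(f"metadata: {exc}")
    for level, path in (table_paths or {}).items():
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            report["errors"].append(f"{level} table unreadable: {exc}")
            continue
        if df.index.duplicated().any():
            report["errors"].append(f"{level} table: duplicate feature ids")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            report["errors"].append(f"{level} table: non-numeric abundances")
        else:
            if (vals < 0).any():
                report["errors"].append(f"{level} table: negative abundances")
            if not np.all(np.isfinite(vals)):
                report["errors"].append(f"{level} table: non-finite abundances")
        if meta is not None:
            missing = [s for s in df.columns if s not in set(meta.sample_ids)]
            if missing:
                report["errors"].append(
                    f"{level} table: samples absent from metadata: {missing[:5]}"
                )
    return report
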