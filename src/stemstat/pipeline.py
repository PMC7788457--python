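"""Pipeline orchestration: config validation and end-to-end stage runs.

A run is described by one declarative (YAML-compatible) config naming the
stages to execute and their parameters.  Stages run in the canonical
order simulate → idmap → enrich → septest → normalize (only those
present in the config), each writing its outputs into the run directory;
the run finishes with a machine-readable JSON report carrying the tool
version, the config echo, the seed and every stage's key numbers — enough
to reproduce the run exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, enrich, idmap, normquant, septest, simgen
from . import io as ssio

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("stemstat")

STAGE_ORDER = ["simulate", "idmap", "enrich", "septest", "normalize", "ddct", "x1"]

_TOP_KEYS = {"seed", "outdir", "log_level", "stages"}

_STAGE_KEYS: dict[str, set[str]] = {
    "simulate": {"T", "n1", "n2", "effects", "noise_sd", "n_genes", "n_true",
                 "prop_down", "n_sets", "set_size", "rho", "n_enriched",
                 "delta", "genome_n_genes", "n_transcripts",
                 "frac_ambiguous", "frac_filtered"},
    "idmap": {"alignments", "annotation", "sets", "min_coverage",
              "min_identity", "fraction", "keep_best", "suffix_pattern"},
    "enrich": {"degs", "sets", "background", "alpha", "lfc", "universe_size"},
    "septest": {"input", "mc_sims"},
    "normalize": {"counts", "zscore"},
    "ddct": {"ct", "control", "efficiency_target", "efficiency_reference"},
    "x1": {"x1", "x2", "xins"},
}


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid config:\n" + "\n".join(f"- {v}" for v in violations))


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: str
    seed: int = 0
    log_level: str = "INFO"
    stages: dict[str, dict] = field(default_factory=dict)


def _validate_dict(cfg: dict) -> tuple[RunConfig | None, list[str]]:
    violations: list[str] = []
    if not isinstance(cfg, dict):
        return None, ["config must be a mapping"]
    for key in sorted(set(cfg) - _TOP_KEYS):
        violations.append(f"unknown key: {key}")
    outdir = cfg.get("outdir")
    if not isinstance(outdir, str) or not outdir:
        violations.append("outdir: required string")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        violations.append("seed: must be an integer")
    log_level = cfg.get("log_level", "INFO")
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        violations.append(f"log_level: unknown level {log_level!r}")
    stages = cfg.get("stages", {})
    if not isinstance(stages, dict):
        violations.append("stages: must be a mapping of stage name to parameters")
        stages = {}
    for name, params in stages.items():
        if name not in _STAGE_KEYS:
            violations.append(f"stages.{name}: unknown stage")
            continue
        if params is None:
            params = {}
        if not isinstance(params, dict):
            violations.append(f"stages.{name}: parameters must be a mapping")
            continue
        for key in sorted(set(params) - _STAGE_KEYS[name]):
            violations.append(f"stages.{name}.{key}: unknown key")
        for size_key in ("n1", "n2", "T", "n_genes", "set_size"):
            v = params.get(size_key)
            if v is not None and (not isinstance(v, int) or v < 1):
                violations.append(f"stages.{name}.{size_key}: must be a positive integer")
        alpha = params.get("alpha")
        if alpha is not None and not (0 < float(alpha) <= 1):
            violations.append(f"stages.{name}.alpha: must be in (0, 1]")
    if violations:
        return None, violations
    return (
        RunConfig(
            outdir=outdir, seed=seed, log_level=log_level,
            stages={k: (v or {}) for k, v in stages.items()},
        ),
        [],
    )


def validate_config(path) -> RunConfig:
    """Parse and schema-check a pipeline config file.

    All violations are collected and reported together, not just the
    first.  Malformed YAML raises with the parser's location message.
    """
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError([f"parse error in {path}: {exc}"]) from exc
    run_cfg, violations = _validate_dict(cfg)
    if violations:
        raise ConfigError(violations)
    return run_cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stage_simulate(params: dict, outdir: Path, seed: int) -> dict:
    tc_kwargs = {k: params[k] for k in ("T", "n1", "n2", "noise_sd") if k in params}
    if "effects" in params:
        tc_kwargs["effects"] = tuple(params["effects"])
    elif "T" in params:
        tc_kwargs["effects"] = (0.0,) * params["T"]
    deg_kwargs = {k: params[k] for k in ("n_genes", "n_true", "prop_down")
                  if k in params}
    set_kwargs = {k: params[k] for k in
                  ("n_sets", "set_size", "rho", "delta", "n_enriched")
                  if k in params}
    gen_kwargs = {k: params[k] for k in
                  ("n_transcripts", "frac_ambiguous", "frac_filtered")
                  if k in params}
    if "genome_n_genes" in params:
        gen_kwargs["n_genes"] = params["genome_n_genes"]
    cfg = simgen.SimConfig(
        seed=seed,
        timecourse=simgen.TimecourseConfig(**tc_kwargs),
        deg=simgen.DEGConfig(**deg_kwargs),
        sets=simgen.SetsConfig(**set_kwargs),
        genome=simgen.GenomeConfig(**gen_kwargs),
    )
    truth = simgen.write_fixture(cfg, outdir)
    return {
        "files": [
            "alignments.bed", "annotation.gff3", "background.txt", "degs.tsv",
            "published.gmt", "sets.gmt", "timecourse.tsv", "truth.json",
        ],
        "n_true_degs": len(truth["deg"]["true_deg_ids"]),
    }


def _stage_septest(params: dict, outdir: Path, seed: int) -> dict:
    path = params.get("input", outdir / "timecourse.tsv")
    tc = septest.GroupedTimeCourse.from_tsv(path)
    result = septest.scan_timecourse(tc)
    out = result.to_dict()
    n_sims = params.get("mc_sims")
    if n_sims and result.k_observed > 0:
        p_mc, se = septest.run_scan_pvalue_mc(
            septest.SeparationParams(
                tc.n1, tc.n2, T=tc.n_timepoints, k=result.k_observed
            ),
            int(n_sims), seed,
        )
        out["p_scan_mc"] = p_mc
        out["p_scan_mc_se"] = se
    with open(outdir / "septest.json", "w") as fh:
        json.dump(out, fh, indent=1)
    return out


def _stage_idmap(params: dict, outdir: Path, seed: int) -> dict:
    records = ssio.read_alignments_bed(params.get("alignments", outdir / "alignments.bed"))
    genes = ssio.read_annotation(params.get("annotation", outdir / "annotation.gff3"))
    mapping = idmap.build_mapping(
        records, genes,
        min_coverage=params.get("min_coverage", 0.9),
        min_identity=params.get("min_identity", 0.9),
        fraction=params.get("fraction", 0.5),
        keep_best=params.get("keep_best", False),
    )
    ssio.write_mapping_tsv(mapping, outdir / "mapping.tsv")
    sets_path = params.get("sets", outdir / "published.gmt")
    mapped_sets = []
    unmapped_counts = {}
    for gs in ssio.read_gmt(sets_path):
        mapped, unmapped = idmap.map_gene_set(
            gs.members, mapping, name=gs.name, source=gs.source,
            suffix_pattern=params.get("suffix_pattern", idmap.DEFAULT_SUFFIX_PATTERN),
        )
        unmapped_counts[gs.name] = len(unmapped)
        if mapped is not None:
            mapped_sets.append(mapped)
    if mapped_sets:
        ssio.write_gmt(enrich.GeneSetCollection(mapped_sets), outdir / "mapped.gmt")
    return {
        "n_assigned": len(mapping.assignments),
        "n_ambiguous": len(mapping.dropped_ambiguous),
        "n_filtered": len(mapping.dropped_filtered),
        "n_unassigned": len(mapping.unassigned),
        "unmapped_per_set": unmapped_counts,
    }


def _stage_enrich(params: dict, outdir: Path, seed: int) -> dict:
    table = enrich.DEGTable.from_tsv(
        params.get("degs", outdir / "degs.tsv"),
        universe_size=params.get("universe_size"),
    )
    sets = ssio.read_gmt(params.get("sets", outdir / "sets.gmt"))
    background = ssio.read_background(params.get("background", outdir / "background.txt"))
    report = enrich.enrich_report(
        table, sets, background,
        alpha=params.get("alpha", 0.05),
        min_abs_lfc=params.get("lfc"),
    )
    report.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {
        "n_sets": len(report),
        "min_p_hyper": float(report["p_hyper"].min()) if len(report) else None,
        "top_set": report.loc[report["p_hyper"].idxmin(), "set"] if len(report) else None,
    }


def _stage_normalize(params: dict, outdir: Path, seed: int) -> dict:
    m = normquant.CountMatrix.from_tsv(params["counts"])
    norm = normquant.normalize_counts(m)
    norm.values.to_csv(outdir / "normalized.tsv", sep="\t")
    out = {"size_factors": {str(k): float(v) for k, v in norm.size_factors.items()}}
    if params.get("zscore"):
        z = normquant.row_zscore(norm.values)
        z.to_csv(outdir / "zscore.tsv", sep="\t")
        out["zscore_file"] = "zscore.tsv"
    return out


def _stage_ddct(params: dict, outdir: Path, seed: int) -> dict:
    t = normquant.CtTable.from_tsv(params["ct"], control_group=params["control"])
    folds = normquant.relative_quantification(
        t,
        efficiency_target=params.get("efficiency_target", 2.0),
        efficiency_reference=params.get("efficiency_reference", 2.0),
    )
    folds.to_frame().to_csv(outdir / "folds.tsv", sep="\t")
    return {"folds": {str(k): float(v) for k, v in folds.items()}}


def _stage_x1(params: dict, outdir: Path, seed: int) -> dict:
    frac = normquant.x1_fraction(
        normquant.FacsFractions(params["x1"], params["x2"], params["xins"])
    )
    return {"x1_fraction": frac}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "idmap": _stage_idmap,
    "enrich": _stage_enrich,
    "septest": _stage_septest,
    "normalize": _stage_normalize,
    "ddct": _stage_ddct,
    "x1": _stage_x1,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in canonical order.

    Returns the run report (also written to ``report.json`` in the run
    directory).  The first failing stage aborts the run with a
    stage-named error.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "stemstat",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "outdir": config.outdir, "seed": config.seed,
            "log_level": config.log_level, "stages": config.stages,
        },
        "stages": {},
        "warnings": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for name in STAGE_ORDER:
        if name not in config.stages:
            continue
        logger.info("running stage %s", name)
        t0 = time.time()
        try:
            out = _STAGE_FUNCS[name](config.stages[name], outdir, config.seed)
        except Exception as exc:  # noqa: BLE001 - reraised with stage name
            raise StageError(name, exc) from exc
        report["stages"][name] = {"result": out, "seconds": round(time.time() - t0, 3)}
    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
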