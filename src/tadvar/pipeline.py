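"""End-to-end orchestration: simulate (or ingest) -> quality gate -> merge ->
ICE -> TAD calling with γ selection -> pairwise scoring -> group statistics.

The pipeline mirrors a cohort reproducibility study: replicate pairs are
scored on per-replicate matrices, non-replicate pairs on merged samples
(configurably depth-matched instead, for null-calibration designs), every
pair receives the three measures (HiCRep SCC with per-pair h selection,
boundary Jaccard, TADsim), and group contrasts are tested with the
Mann–Whitney U test.  A run manifest records the config hash, seed,
excluded samples, per-sample γ and per-pair h so that identical configs
and seeds reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .hic_core import (
    ContactMatrix,
    coverage_quality_check,
    ice_normalize,
    merge_replicates,
    read_contact_matrix,
)
from .similarity import jaccard_index, scc, select_h, tadsim
from .stats_compare import (
    MEASURES,
    DEFAULT_ROBUSTNESS_TARGETS,
    SampleMeta,
    build_pair_table,
    results_to_frame,
    robustness_sweep,
    run_comparison_suite,
)
from .synthetic_data import (
    CohortConfig,
    Cohort,
    SimSample,
    make_cohort,
    protocol_cohort_config,
    replicate_cohort_config,
)
from .tad_caller import (
    DEFAULT_GAMMA_GRID,
    DEFAULT_TARGET_TAD_BASES,
    GammaSweepResult,
    boundaries_of,
    gamma_sweep,
    select_gamma_by_median,
)

logger = logging.getLogger("tadvar")

__all__ = [
    "ConfigError",
    "validate_config",
    "prepare_cohort",
    "score_pairs",
    "score_tad_measures_for_target",
    "run_full_pipeline",
    "PipelineResult",
    "CohortScoring",
]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


_DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "simulate",
    "seed": 0,
    "bin_size": 100_000,
    "gamma_grid": list(DEFAULT_GAMMA_GRID),
    "target_tad_bases": DEFAULT_TARGET_TAD_BASES,
    "robustness_targets": list(DEFAULT_ROBUSTNESS_TARGETS),
    "run_robustness": True,
    "h_range": [0, 3],
    "allow_h_extend": False,
    "h_delta": 0.01,
    "alpha": 0.05,
    "n_null": 1000,
    "tolerance_bins": 0,
    "min_contacts": 1000,
    "min_fraction": 0.8,
    "merge_replicates": True,
    "cohort": {
        "design": "replicate",
        "n_types": 10,
        "n_replicates": 2,
        "perturb_rate": 0.3,
        "n_bins": 300,
        "depth": 250.0,
        "protocol": "in_situ",
        "protocol_longrange_factor": 0.7,
    },
    "ingest": None,
}


def validate_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    """Normalize a pipeline config: inject defaults, reject unknown keys.

    All problems are aggregated into a single :class:`ConfigError`.
    """
    config = dict(config or {})
    problems: list[str] = []
    out = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    for key, value in config.items():
        if key not in _DEFAULT_CONFIG:
            problems.append(f"unknown key {key!r}")
            continue
        if key == "cohort":
            if not isinstance(value, Mapping):
                problems.append("cohort must be a mapping")
                continue
            for ck, cv in value.items():
                if ck not in _DEFAULT_CONFIG["cohort"]:
                    problems.append(f"unknown cohort key {ck!r}")
                else:
                    out["cohort"][ck] = cv
        else:
            out[key] = value

    if out["mode"] not in ("simulate", "ingest"):
        problems.append(f"mode must be simulate or ingest, got {out['mode']!r}")
    try:
        out["gamma_grid"] = [float(g) for g in out["gamma_grid"]]
        if not out["gamma_grid"]:
            problems.append("gamma_grid must be non-empty")
    except (TypeError, ValueError):
        problems.append("gamma_grid must be a list of numbers")
    hr = out["h_range"]
    if (
        not isinstance(hr, (list, tuple))
        or len(hr) != 2
        or not all(isinstance(x, int) for x in hr)
        or hr[0] > hr[1]
        or hr[0] < 0
    ):
        problems.append("h_range must be [lo, hi] with 0 <= lo <= hi")
    elif hr[1] > 3 and not out["allow_h_extend"]:
        problems.append("h_range above 3 requires allow_h_extend")
    for key, lo, hi in (
        ("alpha", 0.0, 1.0),
        ("min_fraction", 0.0, 1.0),
    ):
        v = out[key]
        if not isinstance(v, (int, float)) or not (lo < v <= hi):
            problems.append(f"{key} must be in ({lo}, {hi}]")
    if not isinstance(out["n_null"], int) or out["n_null"] < 100:
        problems.append("n_null must be an integer >= 100")
    if not isinstance(out["seed"], int):
        problems.append("seed must be an integer")
    if out["mode"] == "ingest" and not out["ingest"]:
        problems.append("ingest mode requires an 'ingest' section with samples")
    if problems:
        raise ConfigError("; ".join(problems))
    return out


# ---------------------------------------------------------------------------
# Cohort preparation and scoring
# ---------------------------------------------------------------------------


@dataclass
class EntityData:
    """One scoring unit (a merged sample or a single replicate)."""

    entity_id: str
    norm: ContactMatrix
    sweep: GammaSweepResult


@dataclass
class CohortScoring:
    """Prepared cohort: normalized matrices and cached γ sweeps."""

    cohort: Cohort
    config: dict[str, Any]
    merged_entities: dict[str, EntityData] = field(default_factory=dict)
    replicate_entities: dict[tuple, EntityData] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)
    gamma_selected: dict[str, float] = field(default_factory=dict)
    h_selected: dict[str, int] = field(default_factory=dict)

    @property
    def included_samples(self) -> list[SimSample]:
        return [
            s for s in self.cohort.samples if s.sample_id not in self.excluded_samples
        ]


def _pair_seed(base_seed: int, id_a: str, id_b: str) -> int:
    tag = "|".join(sorted((id_a, id_b)))
    return (int(base_seed) * 100_003 + zlib.crc32(tag.encode())) % (2**31)


def prepare_cohort(cohort: Cohort, config: Mapping[str, Any] | None = None) -> CohortScoring:
    """Quality-gate, merge, ICE-normalize and γ-sweep every scoring unit."""
    cfg = validate_config(config)
    scoring = CohortScoring(cohort=cohort, config=cfg)
    grid = cfg["gamma_grid"]
    for s in cohort.samples:
        merged = s.merged()
        report = coverage_quality_check(
            merged, min_contacts=cfg["min_contacts"], min_fraction=cfg["min_fraction"]
        )
        if not report.passed:
            logger.warning(
                "sample %s fails coverage gate (%.1f%% of bins > %d contacts); excluded",
                s.sample_id, 100 * report.fraction_passing, cfg["min_contacts"],
            )
            scoring.excluded_samples.append(s.sample_id)
            continue
        if cfg["merge_replicates"]:
            rep_entity = merged
        else:
            rep_entity = s.replicates[0]  # depth-matched scoring unit
        norm = ice_normalize(rep_entity).matrix
        sweep = gamma_sweep(norm, grid)
        scoring.merged_entities[s.sample_id] = EntityData(s.sample_id, norm, sweep)
        for ri, rep in enumerate(s.replicates):
            nrm = ice_normalize(rep).matrix
            scoring.replicate_entities[(s.sample_id, ri)] = EntityData(
                f"{s.sample_id}.r{ri}", nrm, gamma_sweep(nrm, grid)
            )
    return scoring


def _tads_for(entity: EntityData, target: int):
    t = select_gamma_by_median(entity.sweep, target)
    return t


def _score_pair(
    ea: EntityData,
    eb: EntityData,
    scoring: CohortScoring,
    target: int,
) -> dict[str, float]:
    cfg = scoring.config
    ta = _tads_for(ea, target)
    tb = _tads_for(eb, target)
    scoring.gamma_selected[ea.entity_id] = ta.gamma
    scoring.gamma_selected[eb.entity_id] = tb.gamma
    ba, bb = boundaries_of(ta), boundaries_of(tb)
    ji = jaccard_index(ba, bb, tolerance_bins=cfg["tolerance_bins"])
    _, cov = tadsim(
        ta, tb, n_bins=ea.norm.n_bins, alpha=cfg["alpha"], n_null=cfg["n_null"],
        seed=_pair_seed(cfg["seed"], ea.entity_id, eb.entity_id),
    )
    hs = list(range(cfg["h_range"][0], cfg["h_range"][1] + 1))
    h = select_h(ea.norm, eb.norm, h_range=hs, delta=cfg["h_delta"])
    scoring.h_selected[f"{ea.entity_id}|{eb.entity_id}"] = h
    val = scc(ea.norm, eb.norm, h=h)
    return {"hicrep": val, "ji": ji, "tadsim": cov}


def score_pairs(scoring: CohortScoring) -> tuple[dict, dict]:
    """Score all replicate pairs and all merged-sample pairs.

    Returns ``(replicate_scores, merged_scores)`` keyed as
    :func:`tadvar.stats_compare.build_pair_table` expects.
    """
    cfg = scoring.config
    target = cfg["target_tad_bases"]
    replicate_scores: dict[tuple, dict[str, float]] = {}
    merged_scores: dict[frozenset, dict[str, float]] = {}
    samples = scoring.included_samples
    for s in samples:
        for ri in range(len(s.replicates)):
            for rj in range(ri + 1, len(s.replicates)):
                ea = scoring.replicate_entities[(s.sample_id, ri)]
                eb = scoring.replicate_entities[(s.sample_id, rj)]
                replicate_scores[(s.sample_id, ri, rj)] = _score_pair(
                    ea, eb, scoring, target
                )
    ids = sorted(e for e in scoring.merged_entities)
    for i, sa in enumerate(ids):
        for sb in ids[i + 1 :]:
            merged_scores[frozenset((sa, sb))] = _score_pair(
                scoring.merged_entities[sa], scoring.merged_entities[sb], scoring, target
            )
    return replicate_scores, merged_scores


def score_tad_measures_for_target(
    scoring: CohortScoring,
    target_bases: int,
    alpha: float = 0.05,
    n_null: int = 1000,
    seed: int | None = 0,
    tolerance_bins: int = 0,
) -> list[dict]:
    """JI and TADsim for every pair at one median-TAD-size target.

    Reuses the cached γ sweeps; only the γ selection changes with the
    target.  Used by the robustness sweep.
    """
    rows: list[dict] = []

    def _do(ea: EntityData, eb: EntityData, is_rep: bool) -> None:
        ta = _tads_for(ea, target_bases)
        tb = _tads_for(eb, target_bases)
        ji = jaccard_index(boundaries_of(ta), boundaries_of(tb), tolerance_bins)
        _, cov = tadsim(
            ta, tb, n_bins=ea.norm.n_bins, alpha=alpha, n_null=n_null,
            seed=_pair_seed(seed or 0, ea.entity_id, eb.entity_id) + target_bases % 97,
        )
        for measure, value in (("ji", ji), ("tadsim", cov)):
            rows.append(
                dict(
                    target_bases=target_bases, measure=measure,
                    id_a=ea.entity_id, id_b=eb.entity_id,
                    is_replicate=is_rep, value=value,
                )
            )

    for s in scoring.included_samples:
        for ri in range(len(s.replicates)):
            for rj in range(ri + 1, len(s.replicates)):
                _do(
                    scoring.replicate_entities[(s.sample_id, ri)],
                    scoring.replicate_entities[(s.sample_id, rj)],
                    True,
                )
    ids = sorted(scoring.merged_entities)
    for i, sa in enumerate(ids):
        for sb in ids[i + 1 :]:
            _do(scoring.merged_entities[sa], scoring.merged_entities[sb], False)
    return rows


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    manifest: dict
    pair_table: pd.DataFrame
    group_tests: pd.DataFrame
    robustness: pd.DataFrame | None
    scoring: CohortScoring


def _config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _cohort_from_config(cfg: dict[str, Any]) -> Cohort:
    c = cfg["cohort"]
    if cfg["mode"] == "ingest":
        return _ingest_cohort(cfg)
    if c["design"] == "protocol":
        cc = protocol_cohort_config(
            n_bins=c["n_bins"], depth=c["depth"], perturb_rate=c["perturb_rate"],
            factor=c["protocol_longrange_factor"], seed=cfg["seed"],
        )
    else:
        cc = replicate_cohort_config(
            n_types=c["n_types"], n_replicates=c["n_replicates"],
            perturb_rate=c["perturb_rate"], n_bins=c["n_bins"], depth=c["depth"],
            seed=cfg["seed"], protocol=c["protocol"],
        )
    return make_cohort(cc)


def _ingest_cohort(cfg: dict[str, Any]) -> Cohort:
    """Load externally produced matrices into the cohort data model."""
    from .synthetic_data import CellTypeSpec, SampleSpec, SimParams, PlantedStructure
    from .tad_caller import TADSet

    entries = cfg["ingest"]["samples"]
    samples: list[SimSample] = []
    n_bins = None
    bin_size = cfg["bin_size"]
    for e in entries:
        reps = [
            read_contact_matrix(
                r["matrix"], r.get("bins"), format=r.get("format", "hicpro_sparse"),
                bin_size=bin_size,
            )
            for r in e["replicates"]
        ]
        n_bins = reps[0].n_bins
        meta = [
            SampleMeta(
                sample_id=e["sample_id"], cell_type=e.get("cell_type", e["sample_id"]),
                is_tissue=e.get("is_tissue", False), donor_id=e.get("donor_id", ""),
                protocol=e.get("protocol", "in_situ"),
                restriction_enzyme=e.get("enzyme", "HindIII"),
                lab=e.get("lab", ""), replicate_index=ri,
            )
            for ri in range(len(reps))
        ]
        truth = PlantedStructure(
            tads=TADSet(chrom=reps[0].chrom, bin_size=reps[0].bin_size, intervals=[]),
            labels=np.full(n_bins, -1, dtype=np.int64),
        )
        samples.append(
            SimSample(
                sample_id=e["sample_id"], cell_type=meta[0].cell_type,
                meta=meta, replicates=reps, truth=truth,
            )
        )
    sim = SimParams(n_bins=n_bins or 1, bin_size=bin_size)
    config = CohortConfig(cell_types=[CellTypeSpec(name="ingest")], sim=sim, seed=cfg["seed"])
    return Cohort(config=config, samples=samples, root_truth=samples[0].truth)


def run_full_pipeline(
    config: Mapping[str, Any] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute all stages and (optionally) write result tables + manifest."""
    cfg = validate_config(config)
    logger.info("pipeline start (seed=%d, mode=%s)", cfg["seed"], cfg["mode"])
    cohort = _cohort_from_config(cfg)
    scoring = prepare_cohort(cohort, cfg)
    replicate_scores, merged_scores = score_pairs(scoring)
    meta = [m for s in scoring.included_samples for m in s.meta]
    pairs = build_pair_table(meta, replicate_scores, merged_scores)
    tests = run_comparison_suite(pairs)
    tests_df = results_to_frame(tests)

    pair_rows = []
    for p in pairs:
        for measure in MEASURES:
            if measure in p.scores:
                pair_rows.append(
                    dict(
                        sample1=p.id_a, sample2=p.id_b, measure=measure,
                        value=p.scores[measure], is_replicate=p.is_replicate,
                        same_cell_type=p.same_cell_type, same_protocol=p.same_protocol,
                    )
                )
    pair_df = pd.DataFrame(pair_rows)

    robustness_df = None
    if cfg["run_robustness"]:
        rob = robustness_sweep(
            scoring, targets_bases=cfg["robustness_targets"], alpha=cfg["alpha"],
            n_null=cfg["n_null"], seed=cfg["seed"], tolerance_bins=cfg["tolerance_bins"],
        )
        robustness_df = rob.scores

    manifest = {
        "tool": "tadvar",
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "n_samples": len(cohort.samples),
        "excluded_samples": sorted(scoring.excluded_samples),
        "gamma_selected": dict(sorted(scoring.gamma_selected.items())),
        "h_selected": dict(sorted(scoring.h_selected.items())),
        "outputs": [],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pair_scores.tsv": pair_df,
            "group_tests.tsv": tests_df,
        }
        if robustness_df is not None:
            paths["robustness.tsv"] = robustness_df
        for name, df in paths.items():
            p = outdir / name
            df.to_csv(p, sep="\t", index=False)
            manifest["outputs"].append(str(p))
        mpath = outdir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["outputs"].append(str(mpath))
    logger.info(
        "pipeline done: %d pairs scored, %d samples excluded",
        len(pairs), len(scoring.excluded_samples),
    )
    return PipelineResult(
        manifest=manifest, pair_table=pair_df, group_tests=tests_df,
        robustness=robustness_df, scoring=scoring,
    )
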