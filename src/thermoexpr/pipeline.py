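"""Two-round campaign orchestration with checkpointing.

The full flow: build (or load) the study system, run a round of independent
SA fits, apply the two compatibility filters, refine the search ranges from
the compatible fits by the Tukey rule, run a second round inside the
refined box, filter again, cluster the compatible fits in parameter space,
and summarize ensemble-level biology.  Every stage writes its result under
the output directory together with a hash of the governing configuration,
so an interrupted run resumes from the last completed stage and a finished
run is fully recomputable from its checkpoints.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annealing_fit import (
    AnnealingConfig,
    FitResult,
    SearchRange,
    refine_search_ranges,
)
from .compat_filters import FilterConfig, apply_all
from .ensemble_analysis import identify_functional_clusters, weighted_site_frequency
from .fit_clustering import cluster_fits
from .io_formats import read_ensemble, write_ensemble
from .synthetic_data import SyntheticScenario, load_scenario, make_fitter, make_scenario

__all__ = ["RunConfig", "run_two_round", "CampaignReport"]

logger = logging.getLogger(__name__)

# fits used for range refinement when fewer than this many pass both filters
_MIN_REFINE_FITS = 4
_FALLBACK_POOL = 10


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a two-round campaign."""

    outdir: str
    seed: int = 0
    preset: str = "eve_like"
    scenario_dir: str | None = None      # load instead of simulate when set
    n_fits: int = 50
    alpha: float | None = None           # None = scenario default
    k_clusters: int | None = None        # None = choose by vote
    annealing: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)

    def annealing_config(self) -> AnnealingConfig:
        base = dict(t_initial=5.0, t_final=1e-2, cooling=0.88,
                    moves_per_temp=30, max_evaluations=1200, polish_maxfev=600)
        base.update(self.annealing)
        return AnnealingConfig(**base)

    def filter_config(self, scenario: SyntheticScenario) -> FilterConfig:
        base = dict(reference_region=tuple(scenario.reference_region),
                    reference_nu=scenario.reference_nu)
        base.update(self.filters)
        if "reference_region" in self.filters:
            base["reference_region"] = tuple(self.filters["reference_region"])
        return FilterConfig(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CampaignReport:
    config: dict
    rounds: list[dict]
    refined_ranges: dict[str, tuple[float, float]]
    clustering: dict
    top_sites: list[dict]

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "rounds": self.rounds,
            "refined_ranges": {k: list(v) for k, v in self.refined_ranges.items()},
            "clustering": self.clustering,
            "top_sites": self.top_sites,
        }


def _config_hash(cfg: RunConfig, stage: str) -> str:
    payload = json.dumps({"cfg": cfg.to_dict(), "stage": stage}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checkpoint_fresh(path: Path, meta: Path, want_hash: str) -> bool:
    if not (path.exists() and meta.exists()):
        return False
    try:
        return json.loads(meta.read_text())["hash"] == want_hash
    except Exception:
        return False


def _mark(meta: Path, want_hash: str) -> None:
    meta.write_text(json.dumps({"hash": want_hash}))


def _refinement_pool(fits: list[FitResult]) -> list[FitResult]:
    """Compatible fits, or the best-RMS fits when too few are compatible."""
    compatible = [f for f in fits if f.compatible]
    if len(compatible) >= _MIN_REFINE_FITS:
        return compatible
    logger.warning(
        "only %d compatible fits; refining from the %d best-RMS fits instead",
        len(compatible), _FALLBACK_POOL,
    )
    return sorted(fits, key=lambda f: f.rms)[:_FALLBACK_POOL]


def run_two_round(cfg: RunConfig) -> CampaignReport:
    """Execute (or resume) the full two-round campaign."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.scenario_dir is not None:
        scenario = load_scenario(cfg.scenario_dir)
    else:
        scenario = make_scenario(cfg.preset, cfg.seed)
    fitter = make_fitter(scenario, alpha=cfg.alpha)
    anneal_cfg = cfg.annealing_config()
    filter_cfg = cfg.filter_config(scenario)

    rounds: list[dict] = []
    ensembles: list[list[FitResult]] = []
    search = scenario.prior_range
    refined: SearchRange | None = None

    for round_id in (1, 2):
        ens_path = outdir / f"ensemble_round{round_id}.jsonl"
        meta = outdir / f"ensemble_round{round_id}.meta.json"
        want = _config_hash(cfg, f"round{round_id}")
        if _checkpoint_fresh(ens_path, meta, want):
            logger.info("round %d: resuming from checkpoint", round_id)
            fits = read_ensemble(ens_path)
        else:
            seed_base = cfg.seed * 1_000_000 + (round_id - 1) * cfg.n_fits
            fits = fitter.ensemble(cfg.n_fits, search, anneal_cfg,
                                   seed_base=seed_base, round_id=round_id)
            fits, _ = apply_all(fits, filter_cfg, fitter.model, fitter.profiles)
            write_ensemble(fits, ens_path)
            _mark(meta, want)
        # recount from the (possibly reloaded) ensemble so the report is
        # always recomputable from checkpoints
        fits, summary = apply_all(fits, filter_cfg, fitter.model, fitter.profiles)
        rounds.append({"round": round_id, **summary.as_dict()})
        ensembles.append(fits)
        if round_id == 1:
            refined = refine_search_ranges(_refinement_pool(fits), search)
            with open(outdir / "refined_ranges.yaml", "w") as fh:
                yaml.safe_dump({k: list(v) for k, v in refined.bounds.items()}, fh)
            search = refined

    compatible = [f for f in ensembles[1] if f.compatible]
    pool = compatible if len(compatible) >= 4 else sorted(
        ensembles[1], key=lambda f: f.rms)[:_FALLBACK_POOL]
    names = search.names
    matrix = np.array([f.params.vector(names) for f in pool])
    assignment = cluster_fits(matrix, seed=cfg.seed, k=cfg.k_clusters)
    np.savetxt(outdir / "pca_coords.csv",
               assignment.pca_coords, delimiter=",",
               header=",".join(f"pc{i + 1}"
                               for i in range(assignment.pca_coords.shape[1])),
               comments="")

    summary = weighted_site_frequency(pool, fitter.model, fitter.profiles,
                                      filter_cfg.reference_nu,
                                      filter_cfg.active_fraction)
    summary.table.to_csv(outdir / "site_summary.csv", index=False)
    best = min(pool, key=lambda f: f.rms)
    fclusters = identify_functional_clusters(best, fitter.model, fitter.profiles,
                                             filter_cfg.reference_nu,
                                             fraction=filter_cfg.active_fraction)
    with open(outdir / "functional_clusters.json", "w") as fh:
        json.dump([
            {"center": c.center, "center_tf": c.center_tf, "rank": c.rank,
             "strength": c.strength,
             "members": [list(m) for m in c.members]}
            for c in fclusters
        ], fh, indent=2)

    report = CampaignReport(
        config=cfg.to_dict(),
        rounds=rounds,
        refined_ranges=dict(refined.bounds),
        clustering={
            "chosen_k": assignment.chosen_k,
            "votes": assignment.votes,
            "low_confidence": assignment.low_confidence,
            "cluster_sizes": {
                str(lab): int((assignment.labels == lab).sum())
                for lab in sorted(set(assignment.labels.tolist()))
            },
            "explained_variance": [float(x) for x in assignment.explained_variance],
        },
        top_sites=summary.table.head(10).to_dict(orient="records"),
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    return report
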