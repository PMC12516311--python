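"""Ensemble-level biology: site frequency maps, functional clusters, and
the competition-window (alpha) sweep.

The weighted site-frequency rule scores each binding site by its summed
contribution to energy-barrier reduction across fits, multiplied by the
number of fits in which it is highly active, normalized by the occurrence
count of the most frequent site, then rescaled so the top site scores 1.

A *functional cluster* is a highly active activator site together with the
quencher and coactivator sites within interaction range that act on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annealing_fit import AnnealingConfig, FitResult, SearchRange
from .compat_filters import FilterConfig, apply_all, highly_active_sites
from .thermo_model import ThermoModel

__all__ = [
    "EnsembleSiteSummary",
    "FunctionalCluster",
    "weighted_site_frequency",
    "aggregate_site_weights",
    "identify_functional_clusters",
    "alpha_sweep",
]


@dataclass(frozen=True)
class EnsembleSiteSummary:
    """Per-site occurrence counts and weighted scores across an ensemble."""

    nu: float
    table: pd.DataFrame  # columns: site_id, tf, start, count, mean_contribution, score

    def score(self, site_id: str) -> float:
        row = self.table[self.table.site_id == site_id]
        return float(row.score.iloc[0]) if len(row) else 0.0

    def top_sites(self, k: int = 10) -> pd.DataFrame:
        return self.table.nlargest(k, "score")


@dataclass(frozen=True)
class FunctionalCluster:
    """An activator site with its in-range quenchers and coactivators.

    ``members`` are (site_id, role, signed distance bp to the center start);
    ``strength`` is the summed activator-channel contribution used for
    ranking (center plus coactivator members).
    """

    center: str
    center_tf: str
    members: tuple[tuple[str, str, int], ...]
    rank: int
    strength: float


def aggregate_site_weights(per_fit_contributions: Sequence[dict]
                           ) -> tuple[dict[str, float], dict[str, int]]:
    """The ensemble weighting rule on per-fit contribution maps.

    ``raw(s) = (sum over fits of contribution_fit(s)) * count(s) / max count``,
    rescaled to [0, 1] by the maximum raw score.  Returns (scores, counts).
    """
    collected: dict[str, list[float]] = {}
    for contribs in per_fit_contributions:
        for sid, c in contribs.items():
            collected.setdefault(sid, []).append(c)
    if not collected:
        return {}, {}
    # exactly rounded sums keep the scores invariant to fit order
    contrib_sum = {s: math.fsum(sorted(v)) for s, v in collected.items()}
    count = {s: len(v) for s, v in collected.items()}
    max_count = max(count.values())
    raw = {s: contrib_sum[s] * count[s] / max_count for s in count}
    max_raw = max(raw.values())
    scores = {s: (r / max_raw if max_raw > 0 else 0.0) for s, r in raw.items()}
    return scores, count


def weighted_site_frequency(fits: Sequence[FitResult], model: ThermoModel,
                            profiles, nu: float, fraction: float = 0.8,
                            layer: str = "RT") -> EnsembleSiteSummary:
    """Score sites by summed contribution x occurrence among highly active sets.

    Applies :func:`aggregate_site_weights` to the major-set contributions of
    each fit.  Only sites appearing in a fit's major set count for that fit.
    """
    if not fits:
        raise ValueError("empty ensemble")
    per_fit = []
    collected: dict[str, list[float]] = {}
    for fit in fits:
        report = highly_active_sites(fit, model, profiles, nu, fraction, layer)
        contribs = {sid: report.contribution(sid) for sid in report.major_set}
        per_fit.append(contribs)
        for sid, c in contribs.items():
            collected.setdefault(sid, []).append(c)
    contrib_sum = {s: math.fsum(sorted(v)) for s, v in collected.items()}
    scores, count = aggregate_site_weights(per_fit)
    rows = []
    for sid in sorted(scores):
        site = model.sitemap.by_id(sid)
        rows.append({
            "site_id": sid,
            "tf": site.tf_name,
            "start": site.start,
            "count": count[sid],
            "mean_contribution": contrib_sum[sid] / count[sid],
            "score": scores[sid],
        })
    table = pd.DataFrame(
        rows, columns=["site_id", "tf", "start", "count",
                       "mean_contribution", "score"]
    ).sort_values(["score", "start"], ascending=[False, True], ignore_index=True)
    return EnsembleSiteSummary(nu=nu, table=table)


def identify_functional_clusters(fit: FitResult, model: ThermoModel, profiles,
                                 nu: float, interaction_range: float | None = None,
                                 fraction: float = 0.8,
                                 layer: str = "RT") -> list[FunctionalCluster]:
    """One cluster per major-set activator at the given nucleus.

    Members are quencher sites whose repression efficiency is nonzero and
    coactivator (edge-source) sites with nonzero occupancy, within
    ``interaction_range`` of the center.  When no explicit range is given,
    each member TF's own fitted action range is used (one source of truth
    with the model layers).  Clusters are ranked by summed activator-channel
    strength, ties broken 5'-most first.
    """
    roles = model.roles
    report = highly_active_sites(fit, model, profiles, nu, fraction, layer)
    grid = profiles.nu_grid
    v = int(np.argmin(np.abs(grid - nu)))
    conc = {tf: profiles.concentrations[tf][v] for tf in profiles.tf_names}
    layers = model.layers(fit.params, conc)
    sites = {s.site_id: s for s in model.sitemap.sites}
    index = {s.site_id: k for k, s in enumerate(model.sitemap.sites)}
    act_tfs = set(roles.activators) | set(roles.coactivation_targets)
    coact_sources = {src for src, _ in roles.coactivation}

    clusters = []
    for sid in report.major_set:
        center = sites[sid]
        if center.tf_name not in act_tfs:
            continue
        members: list[tuple[str, str, int]] = []
        for oid, other in sites.items():
            if oid == sid or other.overlaps(center.start, center.end):
                continue
            dist = other.start - center.start
            gap = center.gap_to(other)
            k = index[oid]
            if (roles.roles[other.tf_name] == "quencher"
                    and layers["repression"][k] > 0):
                rng = (interaction_range if interaction_range is not None
                       else fit.params[f"qrange_{other.tf_name}"])
                if gap <= rng:
                    members.append((oid, "quencher", dist))
            if (center.tf_name in roles.coactivation_targets
                    and other.tf_name in coact_sources
                    and layers["f"][k] > 0):
                for src, tgt in roles.coactivation:
                    if src != other.tf_name or tgt != center.tf_name:
                        continue
                    rng = (interaction_range if interaction_range is not None
                           else fit.params[f"corange_{src}_{tgt}"])
                    if gap <= rng and fit.params[f"Eco_{src}_{tgt}"] > 0:
                        members.append((oid, "coactivator", dist))
        strength = report.contribution(sid)
        for oid, role, _ in members:
            if role == "coactivator":
                strength += report.contribution(oid)
        clusters.append((center, tuple(dict.fromkeys(members)), strength))

    clusters.sort(key=lambda c: (-c[2], c[0].start))
    return [
        FunctionalCluster(center=c.site_id, center_tf=c.tf_name,
                          members=m, rank=r + 1, strength=s)
        for r, (c, m, s) in enumerate(clusters)
    ]


def alpha_sweep(alphas: Sequence[float], fitter_factory, search: SearchRange,
                config: AnnealingConfig, filter_cfg: FilterConfig,
                n_fits: int, seed_base: int = 0,
                refit: bool = True,
                base_fits: Sequence[FitResult] | None = None) -> dict:
    """Re-run (or re-evaluate) the campaign for each competition window size.

    ``fitter_factory(alpha)`` must return an :class:`ExpressionFitter`
    whose model uses that window length.  With ``refit=True`` each alpha
    gets its own ensemble (parameters re-estimated per window size); with
    ``refit=False`` the supplied ``base_fits`` are re-evaluated under each
    alpha.  Returns ``{alpha: {"summary", "site_summary", "fits"}}``.
    """
    if not refit and base_fits is None:
        raise ValueError("refit=False requires base_fits")
    out = {}
    for alpha in alphas:
        fitter = fitter_factory(alpha)
        if refit:
            fits = fitter.ensemble(n_fits, search, config, seed_base=seed_base)
        else:
            fits = [
                FitResult(params=f.params,
                          rms=fitter.cost(f.params),
                          predicted=fitter.predict(f.params),
                          seed=f.seed, round_id=f.round_id)
                for f in base_fits
            ]
        fits, summary = apply_all(fits, filter_cfg, fitter.model, fitter.profiles)
        compatible = [f for f in fits if f.compatible] or list(fits)
        site_summary = weighted_site_frequency(
            compatible, fitter.model, fitter.profiles, filter_cfg.reference_nu,
            filter_cfg.active_fraction, filter_cfg.activity_layer,
        )
        out[float(alpha)] = {
            "summary": summary,
            "site_summary": site_summary,
            "fits": fits,
        }
    return out
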