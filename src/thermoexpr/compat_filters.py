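"""Biological-compatibility filtering of fit ensembles.

Filter 1 keeps fits whose RMS against the observed profile is at or below a
threshold.  Filter 2 asks whether, at the reference nucleus (the stripe-2
expression peak), at least one of the *major activators* — the shortest
prefix of sites, ranked by their share of the total energy-barrier
reduction, reaching the configured fraction (default 80%) — lies inside the
reference enhancer region (default S2E, −1600..−800 bp).  Filter 2 is only
evaluated on filter-1 passers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annealing_fit import FitResult
from .thermo_model import ThermoModel

__all__ = [
    "ActiveSiteReport",
    "FilterConfig",
    "FilterSummary",
    "filter_rms",
    "highly_active_sites",
    "rank_major_sites",
    "filter_region_compatibility",
    "apply_all",
]


@dataclass(frozen=True)
class ActiveSiteReport:
    """Ranked per-site contributions to barrier reduction at one nucleus.

    ``entries`` are (site_id, contribution share, cumulative share) sorted
    by contribution descending (ties broken 5'-first); ``major_set`` is the
    minimal prefix whose cumulative share reaches the target fraction.
    An all-zero activity vector yields an empty, flagged report.
    """

    nu: float
    entries: tuple[tuple[str, float, float], ...]
    major_set: tuple[str, ...]
    no_activation: bool = False

    def contribution(self, site_id: str) -> float:
        for sid, c, _ in self.entries:
            if sid == site_id:
                return c
        return 0.0


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and references for the two compatibility filters."""

    rms_threshold: float = 12.0
    active_fraction: float = 0.8
    reference_region: tuple[float, float] = (-1600.0, -800.0)
    reference_nu: float = 40.5
    activity_layer: str = "RT"  # or "FEaA"

    def __post_init__(self) -> None:
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in (0, 1]")
        if self.activity_layer not in ("RT", "FEaA"):
            raise ValueError(f"unknown activity layer {self.activity_layer!r}")


@dataclass
class FilterSummary:
    n_total: int
    n_pass_rms: int
    n_pass_both: int

    @property
    def frac_pass_rms(self) -> float:
        return self.n_pass_rms / self.n_total if self.n_total else 0.0

    @property
    def frac_pass_both(self) -> float:
        return self.n_pass_both / self.n_total if self.n_total else 0.0

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_pass_rms": self.n_pass_rms,
            "n_pass_both": self.n_pass_both,
            "frac_pass_rms": self.frac_pass_rms,
            "frac_pass_both": self.frac_pass_both,
        }


def filter_rms(fits: Sequence[FitResult], cfg: FilterConfig
               ) -> tuple[list[FitResult], list[FitResult]]:
    """Split fits by the inclusive RMS threshold, recording verdicts."""
    passed, failed = [], []
    for fit in fits:
        ok = fit.rms <= cfg.rms_threshold
        fit.filter1_pass = bool(ok)
        (passed if ok else failed).append(fit)
    return passed, failed


def site_contributions(model: ThermoModel, fit: FitResult, nu: float,
                       profiles, layer: str = "RT") -> np.ndarray:
    """Per-site activity at the grid nucleus closest to ``nu``."""
    grid = profiles.nu_grid
    v = int(np.argmin(np.abs(grid - nu)))
    conc = {tf: profiles.concentrations[tf][v] for tf in profiles.tf_names}
    layers = model.layers(fit.params, conc)
    return np.asarray(layers["RT" if layer == "RT" else "FEaA"])


def rank_major_sites(contributions: Sequence[float], starts: Sequence[float],
                     ids: Sequence[str], fraction: float
                     ) -> tuple[list[tuple[str, float, float]], list[str]]:
    """Normalize, sort and cut a contribution vector at the target fraction.

    Returns (entries, major_ids): entries are (id, share, cumulative share)
    sorted by share descending with ties broken by position (5' first);
    ``major_ids`` is the shortest prefix whose cumulative share reaches
    ``fraction``.  Invariant under positive rescaling of the contributions.
    """
    contributions = np.asarray(contributions, dtype=float)
    total = contributions.sum()
    if total <= 0.0:
        return [], []
    shares = contributions / total
    order = sorted(range(len(shares)), key=lambda i: (-shares[i], starts[i]))
    entries = []
    cum = 0.0
    major: list[str] = []
    reached = False
    for i in order:
        if shares[i] <= 0.0:
            continue
        cum += shares[i]
        entries.append((ids[i], float(shares[i]), float(cum)))
        if not reached:
            major.append(ids[i])
            if cum >= fraction - 1e-12:
                reached = True
    return entries, major


def highly_active_sites(fit: FitResult, model: ThermoModel, profiles,
                        nu: float, fraction: float = 0.8,
                        layer: str = "RT") -> ActiveSiteReport:
    """Rank sites by their share of total barrier reduction at one nucleus.

    Contributions are each site's share of the summed activity layer;
    ``major_set`` is the shortest descending-sorted prefix with cumulative
    share >= ``fraction``.
    """
    activity = site_contributions(model, fit, nu, profiles, layer)
    sites = model.sitemap.sites
    entries, major = rank_major_sites(
        activity, [s.start for s in sites], [s.site_id for s in sites], fraction
    )
    if not entries:
        return ActiveSiteReport(nu=nu, entries=(), major_set=(),
                                no_activation=True)
    return ActiveSiteReport(nu=nu, entries=tuple(entries),
                            major_set=tuple(major))


def filter_region_compatibility(fit: FitResult, cfg: FilterConfig,
                                model: ThermoModel, profiles) -> bool:
    """True iff a major activator intersects the reference enhancer region.

    Coactivated quencher sites count as activators here: they appear in the
    activator channel, so they carry nonzero activity at the reference
    nucleus like any other major-set member.
    """
    report = highly_active_sites(fit, model, profiles, cfg.reference_nu,
                                 cfg.active_fraction, cfg.activity_layer)
    fit.active_sites = report
    if not report.major_set:
        return False
    lo, hi = cfg.reference_region
    for sid in report.major_set:
        site = model.sitemap.by_id(sid)
        if site.start < hi and lo < site.end:
            return True
    return False


def apply_all(fits: Sequence[FitResult], cfg: FilterConfig,
              model: ThermoModel, profiles
              ) -> tuple[list[FitResult], FilterSummary]:
    """Run both filters in order and annotate every fit with its verdicts."""
    passed_rms, failed_rms = filter_rms(fits, cfg)
    for fit in failed_rms:
        fit.filter2_pass = None  # filter 2 is only evaluated on filter-1 passers
    n_both = 0
    for fit in passed_rms:
        ok = filter_region_compatibility(fit, cfg, model, profiles)
        fit.filter2_pass = bool(ok)
        n_both += int(ok)
    summary = FilterSummary(
        n_total=len(fits), n_pass_rms=len(passed_rms), n_pass_both=n_both
    )
    return list(fits), summary
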