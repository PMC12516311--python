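"""The layered thermodynamic forward model of promoter activity.

From a fixed binding-site map, a nucleus's TF concentrations and a
parameter set, the model composes five layers:

``f``
    thermodynamic-equilibrium fractional occupancy of every site, with
    steric exclusion between overlapping sites and homotypic (Bcd–Bcd)
    cooperativity, computed by an interval dynamic program over the
    configuration partition function;
``F``
    occupancy adjusted for short-range quenching and coactivation: each
    bound quencher within its action range multiplicatively reduces nearby
    activators' effective occupancy, while a bound Hb within coactivation
    range of bound Bcd/Cad switches into the activator channel;
``FEaA``
    per-site activating contribution ``F * E_a(tf)``;
``R×T``
    realized contribution after DNA windows of length alpha compete for
    the promoter, each window claiming a share proportional to its total
    activating content;
``M``
    promoter activity through a diffusion-limited Arrhenius law: the sum of
    R×T lowers the activation energy barrier,
    ``M = basal + M_max * exp(-scale * max(theta - sum RT, 0))``.

The free parameters of a configuration are derived from its
:class:`TFRoleTable`; the 8-TF *eve* configuration exposes exactly 32.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .io_formats import ExpressionProfile, TFProfileTable
from .pwm_annotation import SiteMap

__all__ = [
    "ParameterSet",
    "TFRoleTable",
    "ModelConfig",
    "eve_roles",
    "free_parameter_names",
    "ThermoModel",
    "compute_occupancy",
    "apply_coactivation_quenching",
    "activation_efficiency",
    "enhancer_competition",
    "promoter_activity",
    "predict_expression",
]

GLOBAL_PARAMS = ("M_max", "theta", "scale", "basal")


class ParameterSet(Mapping):
    """An immutable named map of model parameter values."""

    def __init__(self, values: Mapping[str, float]):
        self._values = {str(k): float(v) for k, v in values.items()}

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"ParameterSet({self._values!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self._values[n] for n in names], dtype=float)

    @classmethod
    def from_vector(cls, names: Sequence[str], vec: np.ndarray) -> "ParameterSet":
        return cls(dict(zip(names, map(float, vec))))

    def replace(self, **updates: float) -> "ParameterSet":
        d = dict(self._values)
        d.update(updates)
        return ParameterSet(d)


@dataclass(frozen=True)
class TFRoleTable:
    """Regulatory roles: activators, quenchers, coactivation edges,
    homotypic cooperativity.

    ``coactivation`` lists (source activator, target quencher) pairs — in
    the *eve* configuration Bcd→Hb and Cad→Hb, so bound Hb near bound
    Bcd/Cad behaves as an activator.  ``cooperative`` lists TFs with
    homotypic cooperativity (Bcd only here).
    """

    roles: dict[str, str]
    coactivation: tuple[tuple[str, str], ...] = ()
    cooperative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for tf, role in self.roles.items():
            if role not in ("activator", "quencher"):
                raise ValueError(f"unknown role {role!r} for {tf}")
        for src, tgt in self.coactivation:
            if self.roles.get(src) != "activator":
                raise ValueError(f"coactivation source {src} must be an activator")
            if self.roles.get(tgt) != "quencher":
                raise ValueError(f"coactivation target {tgt} must be a quencher")
        for tf in self.cooperative:
            if tf not in self.roles:
                raise ValueError(f"cooperative TF {tf} has no role")

    @property
    def tf_names(self) -> list[str]:
        return list(self.roles)

    @property
    def activators(self) -> list[str]:
        return [tf for tf, r in self.roles.items() if r == "activator"]

    @property
    def quenchers(self) -> list[str]:
        return [tf for tf, r in self.roles.items() if r == "quencher"]

    @property
    def coactivation_targets(self) -> list[str]:
        out = []
        for _, tgt in self.coactivation:
            if tgt not in out:
                out.append(tgt)
        return out


def eve_roles() -> TFRoleTable:
    """The 8-TF *even-skipped* configuration: Bcd/Cad/Dst activate,
    Hb/Gt/Kr/Kni/Tll quench, Hb is coactivated by Bcd and Cad, and only
    Bcd–Bcd cooperativity is considered."""
    return TFRoleTable(
        roles={
            "Bcd": "activator",
            "Cad": "activator",
            "Dst": "activator",
            "Hb": "quencher",
            "Gt": "quencher",
            "Kr": "quencher",
            "Kni": "quencher",
            "Tll": "quencher",
        },
        coactivation=(("Bcd", "Hb"), ("Cad", "Hb")),
        cooperative=("Bcd",),
    )


def free_parameter_names(roles: TFRoleTable) -> list[str]:
    """The ordered free-parameter names exposed to the optimizer.

    Per TF: a binding scale ``K``; per activator an efficacy ``Ea``; per
    coactivation target a distinct coactivated efficacy; per quencher a
    quenching efficiency ``Eq`` and action range; per coactivation edge an
    efficiency and range; per cooperative TF a strength and range; plus the
    four promoter constants.  The *eve* configuration yields 32 names.
    """
    names = [f"K_{tf}" for tf in roles.tf_names]
    names += [f"Ea_{tf}" for tf in roles.activators]
    names += [f"Ea_{tf}_coact" for tf in roles.coactivation_targets]
    names += [f"Eq_{tf}" for tf in roles.quenchers]
    names += [f"Eco_{src}_{tgt}" for src, tgt in roles.coactivation]
    for tf in roles.cooperative:
        names += [f"coop_{tf}_strength", f"coop_{tf}_range"]
    names += [f"qrange_{tf}" for tf in roles.quenchers]
    names += [f"corange_{src}_{tgt}" for src, tgt in roles.coactivation]
    names += list(GLOBAL_PARAMS)
    return names


@dataclass(frozen=True)
class ModelConfig:
    """Run-level model settings that are not free parameters.

    ``alpha`` is the competition window length in bp (held fixed per run,
    swept externally); ``window_mode`` places tiled windows anchored at the
    locus 5' end by default, with an overlapping sliding variant;
    ``competition_capacity`` is the promoter-interaction capacity kappa in
    barrier-reduction units — window content saturates as T/(1 + T/kappa),
    so crowded windows yield diminishing returns per site;
    ``coactivation_variant`` selects whether a coactivated target uses its
    own distinct efficacy (default) or reuses its quenching efficiency.
    """

    alpha: float = 500.0
    window_mode: str = "tiled"
    competition_capacity: float = 1.0
    coactivation_variant: str = "distinct_ea"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.competition_capacity <= 0:
            raise ValueError("competition_capacity must be positive")
        if self.window_mode not in ("tiled", "sliding"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        if self.coactivation_variant not in ("distinct_ea", "convert_eq"):
            raise ValueError(
                f"unknown coactivation_variant {self.coactivation_variant!r}"
            )


class ThermoModel:
    """Vectorized evaluator of the full layer stack on a fixed SiteMap.

    Precomputes site geometry once; each :meth:`predict` call only rebuilds
    the parameter arrays, making it cheap enough for annealing loops.
    """

    def __init__(self, sitemap: SiteMap, roles: TFRoleTable,
                 config: ModelConfig = ModelConfig()):
        unknown = set(sitemap.tf_names) - set(roles.tf_names)
        if unknown:
            raise ValueError(f"unknown TFs in site map: {sorted(unknown)}")
        self.sitemap = sitemap
        self.roles = roles
        self.config = config
        self.tf_order = roles.tf_names
        self._tf_index = {tf: i for i, tf in enumerate(self.tf_order)}
        self.param_names = free_parameter_names(roles)

        sites = list(sitemap.sites)
        # kernel works in end-sorted order; keep the permutation to map back
        order = sorted(range(len(sites)), key=lambda i: (sites[i].end, sites[i].start,
                                                         sites[i].tf_name, sites[i].strand))
        self._perm = np.array(order, dtype=np.int64)
        self._inv = np.argsort(self._perm)
        ss = [sites[i] for i in order]
        n = len(ss)
        self._tfidx = np.array([self._tf_index[s.tf_name] for s in ss], dtype=np.int64)
        self._start = np.array([s.start for s in ss], dtype=np.int64)
        self._end = np.array([s.end for s in ss], dtype=np.int64)
        self._score = np.array([s.norm_score for s in ss], dtype=float)
        gap = np.zeros((n, n))
        overlap = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            for j in range(n):
                g = max(self._start[j] - self._end[i],
                        self._start[i] - self._end[j], 0)
                gap[i, j] = g
                if ss[i].overlaps(ss[j].start, ss[j].end) and i != j:
                    overlap[i, j] = 1
        self._gap = gap
        self._overlap = overlap

        act = set(roles.activators)
        targets = set(roles.coactivation_targets)
        self._act_channel = np.array(
            [1 if s.tf_name in act else 0 for s in ss], dtype=np.uint8
        )
        self._coact_channel = np.array(
            [1 if s.tf_name in targets else 0 for s in ss], dtype=np.uint8
        )
        self._edge_src = np.array(
            [self._tf_index[s] for s, _ in roles.coactivation], dtype=np.int64
        )
        self._edge_tgt = np.array(
            [self._tf_index[t] for _, t in roles.coactivation], dtype=np.int64
        )
        lo, hi = sitemap.locus.locus_span
        self._locus_lo, self._locus_hi = lo, hi
        self._win_id = self._window_ids(config.alpha)

    # -- parameter unpacking -------------------------------------------------

    def _window_ids(self, alpha: float) -> np.ndarray:
        span = self._locus_hi - self._locus_lo
        if alpha >= span:
            return np.zeros(len(self._start), dtype=np.int64)
        return ((self._start - self._locus_lo) // int(alpha)).astype(np.int64)

    def _unpack(self, params: ParameterSet):
        r = self.roles
        n_tf = len(self.tf_order)
        K = np.zeros(n_tf)
        Eq = np.zeros(n_tf)
        qr = np.zeros(n_tf)
        Ea_tf = np.zeros(n_tf)
        for tf, i in self._tf_index.items():
            K[i] = params[f"K_{tf}"]
            if r.roles[tf] == "quencher":
                Eq[i] = params[f"Eq_{tf}"]
                qr[i] = params[f"qrange_{tf}"]
            if r.roles[tf] == "activator":
                Ea_tf[i] = params[f"Ea_{tf}"]
        for tgt in r.coactivation_targets:
            if self.config.coactivation_variant == "distinct_ea":
                Ea_tf[self._tf_index[tgt]] = params[f"Ea_{tgt}_coact"]
            else:  # convert_eq: the coactivated target reuses its Eq as efficacy
                Ea_tf[self._tf_index[tgt]] = params[f"Eq_{tgt}"]
        Ea_site = Ea_tf[self._tfidx]
        Eco = np.array([params[f"Eco_{s}_{t}"] for s, t in r.coactivation])
        corange = np.array([params[f"corange_{s}_{t}"] for s, t in r.coactivation])
        if r.cooperative:
            tf = r.cooperative[0]
            coop = (self._tf_index[tf], params[f"coop_{tf}_strength"],
                    params[f"coop_{tf}_range"])
        else:
            coop = (-1, 1.0, 0.0)
        return K, Ea_site, Eq, qr, Eco, corange, coop

    # -- evaluation ----------------------------------------------------------

    def _layers_raw(self, params: ParameterSet, conc: np.ndarray):
        """f, F, FEaA, rep in end-sorted order, shape (n_sites, n_nu)."""
        K, Ea_site, Eq, qr, Eco, corange, coop = self._unpack(params)
        return _kernels.forward_layers(
            np.ascontiguousarray(conc, dtype=float),
            self._tfidx, self._start, self._end, self._score,
            self._gap, self._overlap,
            self._act_channel, self._coact_channel,
            K, Ea_site, Eq, qr,
            self._edge_src, self._edge_tgt, Eco, corange,
            coop[0], coop[1], coop[2],
        )

    def _competition(self, FE: np.ndarray) -> np.ndarray:
        """R×T from FEaA: sites within one alpha-window compete for the
        promoter's limited interaction capacity.

        A window with total activating content T realizes T / (1 + T/kappa)
        of it, so each member site keeps the fraction R = 1 / (1 + T/kappa).
        The form is monotone in every site's FEaA and never exceeds it.
        """
        kappa = self.config.competition_capacity
        if self.config.window_mode == "tiled":
            n_win = int(self._win_id.max()) + 1 if len(self._win_id) else 1
            T = np.zeros((n_win, FE.shape[1]))
            np.add.at(T, self._win_id, FE)
            share = 1.0 / (1.0 + T[self._win_id] / kappa)
        else:  # sliding: per-site window centered on the site
            centers = (self._start + self._end) / 2.0
            within = np.abs(centers[:, None] - centers[None, :]) <= self.config.alpha / 2.0
            T = within @ FE  # (n, m)
            share = 1.0 / (1.0 + T / kappa)
        return FE * share

    def _promoter(self, RT: np.ndarray, params: ParameterSet) -> np.ndarray:
        srt = RT.sum(axis=0)
        barrier = np.maximum(params["theta"] - srt, 0.0)
        return params["basal"] + params["M_max"] * np.exp(-params["scale"] * barrier)

    def layers(self, params: ParameterSet, conc_by_tf: Mapping[str, float]):
        """All per-site layer values at one nucleus, in SiteMap order.

        Returns a dict of arrays ``f, F, FEaA, RT, repression`` aligned to
        ``self.sitemap.sites`` plus the scalar promoter activity ``M``.
        """
        conc = np.array([[conc_by_tf.get(tf, 0.0)] for tf in self.tf_order])
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        f, F, FE, rep = self._layers_raw(params, conc)
        RT = self._competition(FE)
        M = self._promoter(RT, params)
        inv = self._inv
        return {
            "f": f[inv, 0],
            "F": F[inv, 0],
            "FEaA": FE[inv, 0],
            "RT": RT[inv, 0],
            "repression": rep[inv, 0],
            "M": float(M[0]),
        }

    def predict(self, params: ParameterSet, profiles: TFProfileTable) -> ExpressionProfile:
        """Model expression M_nu over the profile grid."""
        missing = set(self.tf_order) - set(profiles.tf_names)
        if missing:
            raise ValueError(f"profiles missing TFs: {sorted(missing)}")
        conc = profiles.matrix(self.tf_order)
        _, _, FE, _ = self._layers_raw(params, conc)
        RT = self._competition(FE)
        return ExpressionProfile(profiles.nu_grid, self._promoter(RT, params))

    def layer_table(self, params: ParameterSet, profiles: TFProfileTable,
                    nu: float | None = None) -> pd.DataFrame:
        """Per-site, per-nucleus layer dump (tabular analogue of the model's
        layer diagram): columns site_id, tf, start, strand, nu, f, F, FEaA,
        RT, repression."""
        conc = profiles.matrix(self.tf_order)
        f, F, FE, rep = self._layers_raw(params, conc)
        RT = self._competition(FE)
        inv = self._inv
        rows = []
        grid = profiles.nu_grid
        sel = range(len(grid)) if nu is None else [int(np.argmin(np.abs(grid - nu)))]
        for v in sel:
            for k, s in enumerate(self.sitemap.sites):
                rows.append({
                    "site_id": s.site_id, "tf": s.tf_name, "start": s.start,
                    "strand": s.strand, "nu": grid[v],
                    "f": f[inv[k], v], "F": F[inv[k], v],
                    "FEaA": FE[inv[k], v], "RT": RT[inv[k], v],
                    "repression": rep[inv[k], v],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Functional layer API (single nucleus); thin wrappers over the engine so the
# algebra has one home.

def _engine(sitemap: SiteMap, roles: TFRoleTable, config: ModelConfig) -> ThermoModel:
    return ThermoModel(sitemap, roles, config)


def compute_occupancy(sitemap: SiteMap, conc: Mapping[str, float],
                      params: ParameterSet, roles: TFRoleTable,
                      config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Fractional occupancy f of every site (SiteMap order) at one nucleus."""
    eng = _engine(sitemap, roles, config)
    return eng.layers(params, conc)["f"]


def _channel_split(f: np.ndarray, sitemap: SiteMap, roles: TFRoleTable,
                   params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Split occupancy into activator channel A and quencher channel q.

    A bound coactivation target contributes to the activator channel with
    the probability that at least one in-range source site is bound and
    coactivating; the remainder keeps quenching.
    """
    sites = list(sitemap.sites)
    n = len(sites)
    f = np.asarray(f, dtype=float)
    A = np.zeros(n)
    q = np.zeros(n)
    targets = set(roles.coactivation_targets)
    for i, s in enumerate(sites):
        role = roles.roles[s.tf_name]
        if role == "activator":
            A[i] = f[i]
        elif s.tf_name in targets:
            p_nocoact = 1.0
            for src, tgt in roles.coactivation:
                if tgt != s.tf_name:
                    continue
                eco = params[f"Eco_{src}_{tgt}"]
                rng = params[f"corange_{src}_{tgt}"]
                for j, s2 in enumerate(sites):
                    if j == i or s2.tf_name != src:
                        continue
                    if s2.overlaps(s.start, s.end):
                        continue
                    if s.gap_to(s2) <= rng:
                        p_nocoact *= 1.0 - eco * f[j]
            A[i] = f[i] * (1.0 - p_nocoact)
            q[i] = f[i] * p_nocoact
        else:
            q[i] = f[i]
    return A, q


def apply_coactivation_quenching(f: np.ndarray, sitemap: SiteMap,
                                 roles: TFRoleTable, params: ParameterSet,
                                 config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Coactivation/quenching-adjusted occupancy F (SiteMap order).

    Each bound quencher within its action range reduces the activator
    channel of a nearby site multiplicatively by ``1 - E_q * f_q``.
    """
    sites = list(sitemap.sites)
    A, q = _channel_split(f, sitemap, roles, params)
    F = np.zeros(len(sites))
    for i, s in enumerate(sites):
        if A[i] <= 0.0:
            continue
        red = 1.0
        for j, s2 in enumerate(sites):
            if j == i or q[j] <= 0.0 or s2.overlaps(s.start, s.end):
                continue
            if s.gap_to(s2) <= params[f"qrange_{s2.tf_name}"]:
                red *= 1.0 - params[f"Eq_{s2.tf_name}"] * q[j]
        F[i] = A[i] * red
    return F


def activation_efficiency(F: np.ndarray, sitemap: SiteMap, params: ParameterSet,
                          roles: TFRoleTable,
                          config: ModelConfig = ModelConfig()) -> np.ndarray:
    """Per-site activating contribution FEaA = F * E_a(tf)."""
    Ea = np.zeros(len(sitemap))
    variant = config.coactivation_variant
    for k, s in enumerate(sitemap.sites):
        if roles.roles[s.tf_name] == "activator":
            Ea[k] = params[f"Ea_{s.tf_name}"]
        elif s.tf_name in roles.coactivation_targets:
            Ea[k] = (params[f"Ea_{s.tf_name}_coact"] if variant == "distinct_ea"
                     else params[f"Eq_{s.tf_name}"])
    return np.asarray(F) * Ea


def enhancer_competition(FEaA: np.ndarray, sitemap: SiteMap, alpha: float,
                         params: ParameterSet, roles: TFRoleTable,
                         window_mode: str = "tiled") -> np.ndarray:
    """R×T: per-site realized contribution after window competition."""
    cfg = ModelConfig(alpha=alpha, window_mode=window_mode)
    eng = _engine(sitemap, roles, cfg)
    FE = np.asarray(FEaA, dtype=float)[eng._perm][:, None]
    return eng._competition(FE)[eng._inv, 0]


def promoter_activity(RT: np.ndarray, params: ParameterSet) -> float:
    """Arrhenius promoter law: total R×T lowers the activation barrier."""
    srt = float(np.sum(RT))
    barrier = max(params["theta"] - srt, 0.0)
    return float(params["basal"] + params["M_max"] * np.exp(-params["scale"] * barrier))


def predict_expression(sitemap: SiteMap, profiles: TFProfileTable,
                       params: ParameterSet, roles: TFRoleTable,
                       config: ModelConfig = ModelConfig()) -> ExpressionProfile:
    """Full-profile model prediction M_nu (composition of all layers)."""
    return ThermoModel(sitemap, roles, config).predict(params, profiles)
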