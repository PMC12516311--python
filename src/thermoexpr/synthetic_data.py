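"""Self-contained synthetic fixtures emulating the blastoderm stripe system.

A scenario bundles a toy locus with planted consensus binding sites, sharp
synthetic PWMs, smooth anterior/posterior TF gradients with gap-gene-like
domains, ground-truth model parameters whose forward prediction drives a
stripe at the reference nucleus, and a noisy "observed" expression profile.
Three presets:

``minimal``
    one activator + one quencher on a ~2 kb locus with at most 12 sites,
    small enough for exhaustive partition-function enumeration;
``eve_like``
    the 8-TF configuration (Bcd/Cad/Dst activate; Hb/Gt/Kr/Kni/Tll quench;
    Hb coactivated by Bcd/Cad; Bcd–Bcd cooperativity) with a planted
    stripe-2-like enhancer at −1600..−800 bp and a decoy upstream region;
``two_logic``
    two alternative planted enhancer regions, each sufficient to drive the
    stripe under its own parameter regime, for fit-clustering tests.

Everything is generated from a single integer seed; regeneration is
bitwise reproducible.  Background sequence is scrubbed so that, at the
scenario's scan threshold, exactly the planted sites are recovered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .annealing_fit import ExpressionFitter, SearchRange
from .io_formats import (
    ExpressionProfile,
    LocusSequence,
    PWMatrix,
    TFProfileTable,
    write_expression,
    write_fasta,
    write_profiles,
    write_pwm,
    write_regions,
)
from .pwm_annotation import scan_sites
from .thermo_model import (
    ModelConfig,
    ParameterSet,
    TFRoleTable,
    ThermoModel,
    eve_roles,
    free_parameter_names,
)

__all__ = [
    "SyntheticScenario",
    "make_scenario",
    "realize",
    "load_scenario",
    "build_model",
    "make_fitter",
    "two_logic_ensemble",
    "NU_GRID",
]

NU_GRID = np.round(np.arange(35.5, 93.0, 1.0), 1)  # 35.5 .. 92.5 %EL, 58 nuclei

_BASES = "ACGT"

# asymmetric consensus motifs (reverse complements score poorly on purpose)
_CONSENSUS = {
    "Bcd": "TAATCCC",
    "Cad": "TTTATGGC",
    "Dst": "TTCCCGGA",
    "Hb": "CATAAAAA",
    "Gt": "TTACGCAA",
    "Kr": "AACGGGTT",
    "Kni": "AACTAGCC",
    "Tll": "AAGTCAAG",
    "Act": "TGGACATC",
    "Rep": "CCATTGAC",
}


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified synthetic study system."""

    preset: str
    seed: int
    locus: LocusSequence
    pwms: tuple[PWMatrix, ...]
    roles: TFRoleTable
    profiles: TFProfileTable
    true_params: ParameterSet
    noise_sd: float
    scan_threshold: float
    model_config: ModelConfig
    reference_region: tuple[float, float]
    reference_nu: float
    planted: tuple[tuple[str, int], ...]        # (tf, locus start)
    expression_true: ExpressionProfile
    expression: ExpressionProfile               # observed = true + noise, clipped at 0
    prior_range: SearchRange                    # wide a-priori round-1 box
    true_range: SearchRange                     # tight box around the truth
    alt_params: ParameterSet | None = None      # second regulatory logic


# ---------------------------------------------------------------------------
# construction helpers

def _make_pwm(tf: str, consensus: str) -> PWMatrix:
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, _BASES.index(b)] = 12.0
    return PWMatrix.from_counts(tf, counts, pseudocount=1.0)


def _gauss(nu: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((nu - center) ** 2) / (2.0 * width**2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _plant(seq: list[str], locus_offset: int, planted: list[tuple[str, int]]) -> None:
    for tf, start in planted:
        motif = _CONSENSUS[tf]
        idx = start + locus_offset
        seq[idx : idx + len(motif)] = list(motif)


def _scrub(seq: list[str], locus_offset: int, pwms, planted, threshold: float,
           closed, rng: np.random.Generator, max_rounds: int = 60) -> str:
    """Mutate background bases until only planted sites pass the threshold."""
    planted_keys = {(tf, start) for tf, start in planted}
    protected = set()
    for tf, start in planted:
        for k in range(len(_CONSENSUS[tf])):
            protected.add(start + locus_offset + k)
    for _ in range(max_rounds):
        locus = LocusSequence("".join(seq), origin_offset=locus_offset,
                             closed_regions=tuple(closed))
        smap = scan_sites(locus, list(pwms), threshold)
        spurious = [
            s for s in smap.sites
            if not (s.strand == "+" and (s.tf_name, s.start) in planted_keys)
        ]
        if not spurious:
            return "".join(seq)
        progress = False
        for s in spurious:
            idxs = [i for i in range(s.start + locus_offset, s.end + locus_offset)
                    if i not in protected]
            if not idxs:
                continue
            i = int(rng.choice(idxs))
            old = seq[i]
            seq[i] = rng.choice([b for b in _BASES if b != old])
            progress = True
        if not progress:
            raise RuntimeError("cannot scrub spurious site overlapping planted motifs")
    raise RuntimeError("scrubbing did not converge")


def _range_around(value: float, rel: float = 0.4, floor: float = 0.0,
                  min_span: float = 1e-3) -> tuple[float, float]:
    lo = max(floor, value * (1 - rel))
    hi = value * (1 + rel)
    if hi - lo < min_span:
        hi = lo + min_span
    return lo, hi


def _true_range(params: ParameterSet, names) -> SearchRange:
    return SearchRange({n: _range_around(params[n]) for n in names})


def _prior_range(roles: TFRoleTable) -> SearchRange:
    """Wide a-priori bounds used for the first annealing round."""
    bounds: dict[str, tuple[float, float]] = {}
    for name in free_parameter_names(roles):
        if name.startswith("K_"):
            bounds[name] = (0.0, 0.2)
        elif name.startswith(("Ea_", "Eq_", "Eco_")):
            bounds[name] = (0.0, 1.0)
        elif name.endswith("_strength"):
            bounds[name] = (1.0, 8.0)
        elif name.endswith("_range") or name.startswith(("qrange_", "corange_")):
            bounds[name] = (30.0, 250.0)
        elif name == "M_max":
            bounds[name] = (50.0, 200.0)
        elif name == "theta":
            bounds[name] = (0.5, 10.0)
        elif name == "scale":
            bounds[name] = (0.1, 5.0)
        elif name == "basal":
            bounds[name] = (0.0, 10.0)
        else:  # pragma: no cover
            raise ValueError(f"no prior for parameter {name}")
    return SearchRange(bounds)


# ---------------------------------------------------------------------------
# presets

def _minimal(seed: int) -> SyntheticScenario:
    roles = TFRoleTable(roles={"Act": "activator", "Rep": "quencher"})
    pwms = (_make_pwm("Act", _CONSENSUS["Act"]), _make_pwm("Rep", _CONSENSUS["Rep"]))
    offset = 1600
    length = 2000
    planted = [
        ("Act", -1500), ("Act", -1300), ("Act", -1100),
        ("Rep", -1380), ("Rep", -1050),
    ]
    closed = [(-600, -300)]
    nu = NU_GRID
    profiles = TFProfileTable(nu, {
        "Act": 100.0 * _gauss(nu, 40.5, 8.0),
        "Rep": 80.0 * _sigmoid((nu - 60.0) / 5.0),
    })
    true_params = ParameterSet({
        "K_Act": 0.05, "K_Rep": 0.04,
        "Ea_Act": 0.9, "Eq_Rep": 0.8, "qrange_Rep": 120.0,
        "M_max": 100.0, "theta": 0.7, "scale": 3.0, "basal": 2.0,
    })
    return _assemble("minimal", seed, roles, pwms, offset, length, planted,
                     closed, profiles, true_params, noise_sd=3.0,
                     scan_threshold=0.9, reference_region=(-1600.0, -800.0),
                     reference_nu=40.5, alpha=800.0)


_EVE_PLANTED = [
    # stripe-2-like enhancer (S2E analogue, -1600..-800)
    ("Gt", -1560), ("Bcd", -1500), ("Hb", -1460), ("Bcd", -1400),
    ("Hb", -1320), ("Bcd", -1260), ("Dst", -1150), ("Kr", -1080),
    ("Kni", -900), ("Gt", -1210),
    # decoy upstream region (-2900..-2400), silenced by Hb/Kr quenching
    ("Gt", -2860), ("Dst", -2800), ("Hb", -2750), ("Kr", -2700),
    ("Tll", -2480),
    # promoter-proximal posterior module, quenched at stripe-2 positions
    ("Cad", -520), ("Kni", -470), ("Tll", -400), ("Gt", -300),
]


def _eve_profiles(nu: np.ndarray) -> TFProfileTable:
    return TFProfileTable(nu, {
        "Bcd": 120.0 * np.exp(-(nu - 35.5) / 18.0),
        "Cad": 90.0 * _sigmoid((nu - 62.0) / 5.0),
        "Dst": np.full_like(nu, 45.0),
        "Hb": 95.0 * _sigmoid((47.0 - nu) / 2.5) + 60.0 * _gauss(nu, 88.0, 4.0),
        "Gt": 90.0 * _gauss(nu, 34.5, 1.8) + 55.0 * _gauss(nu, 77.0, 4.0),
        "Kr": 85.0 * _gauss(nu, 52.0, 5.0),
        "Kni": 75.0 * _gauss(nu, 66.0, 4.0),
        "Tll": 85.0 * _sigmoid((nu - 86.0) / 2.0),
    })


_EVE_TRUE = {
    "K_Bcd": 0.05, "K_Cad": 0.05, "K_Dst": 0.06, "K_Hb": 0.04,
    "K_Gt": 0.08, "K_Kr": 0.06, "K_Kni": 0.05, "K_Tll": 0.05,
    "Ea_Bcd": 0.5, "Ea_Cad": 0.55, "Ea_Dst": 0.5, "Ea_Hb_coact": 0.8,
    "Eq_Hb": 0.8, "Eq_Gt": 0.9, "Eq_Kr": 0.85, "Eq_Kni": 0.8, "Eq_Tll": 0.85,
    "Eco_Bcd_Hb": 0.9, "Eco_Cad_Hb": 0.5,
    "coop_Bcd_strength": 3.0, "coop_Bcd_range": 60.0,
    "qrange_Hb": 150.0, "qrange_Gt": 120.0, "qrange_Kr": 150.0,
    "qrange_Kni": 100.0, "qrange_Tll": 150.0,
    "corange_Bcd_Hb": 150.0, "corange_Cad_Hb": 150.0,
    "M_max": 100.0, "theta": 1.3, "scale": 2.5, "basal": 2.0,
}


def _eve_like(seed: int) -> SyntheticScenario:
    roles = eve_roles()
    pwms = tuple(_make_pwm(tf, _CONSENSUS[tf]) for tf in roles.tf_names)
    return _assemble("eve_like", seed, roles, pwms, offset=3000, length=3200,
                     planted=list(_EVE_PLANTED), closed=[(-2300, -1900)],
                     profiles=_eve_profiles(NU_GRID),
                     true_params=ParameterSet(_EVE_TRUE), noise_sd=3.0,
                     scan_threshold=0.9, reference_region=(-1600.0, -800.0),
                     reference_nu=40.5, alpha=800.0)


_TWO_LOGIC_PLANTED = [
    # logic A: S2E analogue driven by Bcd + coactivated Hb
    ("Gt", -1560), ("Bcd", -1500), ("Hb", -1460), ("Bcd", -1400),
    ("Hb", -1320), ("Bcd", -1260), ("Gt", -1210), ("Kr", -1100),
    ("Kni", -1020),
    # logic B: alternative enhancer driven by Dst, with its own full set of
    # spatial borders (Gt anterior, Kr central, Kni/Tll posterior)
    ("Gt", -2860), ("Dst", -2800), ("Tll", -2750), ("Kni", -2720),
    ("Kr", -2680),
    ("Gt", -2560), ("Dst", -2500), ("Kni", -2450), ("Kr", -2420),
    ("Tll", -2380),
]

_TWO_LOGIC_A = {
    **_EVE_TRUE,
    "Ea_Dst": 0.02,        # alternative region inert under logic A
}

_TWO_LOGIC_B = {
    **_EVE_TRUE,
    "Ea_Bcd": 0.03, "Ea_Cad": 0.05, "Ea_Hb_coact": 0.02,
    "Eco_Bcd_Hb": 0.05, "Eco_Cad_Hb": 0.05,
    "Ea_Dst": 0.8,         # alternative region drives the stripe
}


def _two_logic(seed: int) -> SyntheticScenario:
    roles = eve_roles()
    pwms = tuple(_make_pwm(tf, _CONSENSUS[tf]) for tf in roles.tf_names)
    sc = _assemble("two_logic", seed, roles, pwms, offset=3000, length=3200,
                   planted=list(_TWO_LOGIC_PLANTED), closed=[],
                   profiles=_eve_profiles(NU_GRID),
                   true_params=ParameterSet(_TWO_LOGIC_A), noise_sd=3.0,
                   scan_threshold=0.9, reference_region=(-1600.0, -800.0),
                   reference_nu=40.5, alpha=800.0)
    return dataclasses.replace(sc, alt_params=ParameterSet(_TWO_LOGIC_B))


def _assemble(preset, seed, roles, pwms, offset, length, planted, closed,
              profiles, true_params, noise_sd, scan_threshold,
              reference_region, reference_nu, alpha) -> SyntheticScenario:
    rng = np.random.default_rng([seed, 0xC0FFEE])
    seq = list(rng.choice(list(_BASES), size=length))
    _plant(seq, offset, planted)
    sequence = _scrub(seq, offset, pwms, planted, scan_threshold, closed, rng)
    locus = LocusSequence(sequence, origin_offset=offset,
                          closed_regions=tuple(closed))
    config = ModelConfig(alpha=alpha)
    sitemap = scan_sites(locus, list(pwms), scan_threshold)
    model = ThermoModel(sitemap, roles, config)
    m_true = model.predict(true_params, profiles)
    noise_rng = np.random.default_rng([seed, 0x5EED])
    noisy = np.clip(
        m_true.values + noise_rng.normal(0.0, noise_sd, size=m_true.values.shape),
        0.0, None,
    )
    names = free_parameter_names(roles)
    return SyntheticScenario(
        preset=preset, seed=seed, locus=locus, pwms=tuple(pwms), roles=roles,
        profiles=profiles, true_params=true_params, noise_sd=noise_sd,
        scan_threshold=scan_threshold, model_config=config,
        reference_region=reference_region, reference_nu=reference_nu,
        planted=tuple(planted), expression_true=m_true,
        expression=ExpressionProfile(m_true.nu_grid, noisy),
        prior_range=_prior_range(roles),
        true_range=_true_range(true_params, names),
    )


_PRESETS = {"minimal": _minimal, "eve_like": _eve_like, "two_logic": _two_logic}


def make_scenario(preset: str, seed: int = 0) -> SyntheticScenario:
    """Build a preset scenario deterministically from a seed."""
    try:
        builder = _PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return builder(seed)


# ---------------------------------------------------------------------------
# model / fitter helpers

def build_model(scenario: SyntheticScenario,
                alpha: float | None = None) -> ThermoModel:
    cfg = (scenario.model_config if alpha is None
           else dataclasses.replace(scenario.model_config, alpha=alpha))
    sitemap = scan_sites(scenario.locus, list(scenario.pwms),
                         scenario.scan_threshold)
    return ThermoModel(sitemap, scenario.roles, cfg)


def make_fitter(scenario: SyntheticScenario, alpha: float | None = None,
                noise_free: bool = False) -> ExpressionFitter:
    observed = scenario.expression_true if noise_free else scenario.expression
    return ExpressionFitter(build_model(scenario, alpha), scenario.profiles,
                            observed)


def two_logic_ensemble(scenario: SyntheticScenario, n_per_logic: int = 15,
                       seed: int = 0, spread: float = 0.05):
    """A synthetic compatible ensemble mixing the two planted logics.

    Each fit perturbs one of the two ground-truth parameter sets
    multiplicatively (lognormal-ish, ``spread`` relative sd) and is
    evaluated through the forward model.  Returns (fits, true_labels).
    """
    from .annealing_fit import FitResult, rms_cost

    if scenario.alt_params is None:
        raise ValueError("scenario has no alternative logic")
    fitter = make_fitter(scenario)
    rng = np.random.default_rng([seed, 0x7107])
    fits, labels = [], []
    for logic, base in enumerate((scenario.true_params, scenario.alt_params)):
        for k in range(n_per_logic):
            factors = np.exp(rng.normal(0.0, spread, size=len(base)))
            params = ParameterSet(
                {name: v * f for (name, v), f in zip(base.items(), factors)}
            )
            predicted = fitter.predict(params)
            fits.append(FitResult(
                params=params,
                rms=rms_cost(scenario.expression, predicted),
                predicted=predicted,
                seed=seed * 1000 + k, round_id=1,
                filter1_pass=True, filter2_pass=True,
            ))
            labels.append(logic)
    return fits, np.array(labels)


# ---------------------------------------------------------------------------
# on-disk realization

def realize(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Write the scenario as the standard file formats.

    Emits FASTA, per-TF JASPAR matrices, concentration and expression CSVs
    (noisy observed and noise-free), BED for the reference region and
    closed chromatin, and a YAML manifest with roles, parameters and
    ranges.  Files round-trip through :mod:`thermoexpr.io_formats`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "locus.fa"
    write_fasta(scenario.locus, paths["fasta"], name=scenario.preset)
    off = scenario.locus.origin_offset
    paths["closed_bed"] = outdir / "closed_chromatin.bed"
    write_regions([(a, b, "closed") for a, b in scenario.locus.closed_regions],
                  paths["closed_bed"], origin_offset=off)
    paths["regions_bed"] = outdir / "regions.bed"
    lo, hi = scenario.reference_region
    write_regions([(int(lo), int(hi), "S2E")], paths["regions_bed"],
                  origin_offset=off)
    for pwm in scenario.pwms:
        p = outdir / f"pwm_{pwm.tf_name}.jaspar"
        write_pwm(pwm, p)
        paths[f"pwm_{pwm.tf_name}"] = p
    paths["profiles"] = outdir / "profiles.csv"
    write_profiles(scenario.profiles, paths["profiles"])
    paths["expression"] = outdir / "expression.csv"
    write_expression(scenario.expression, paths["expression"])
    paths["expression_true"] = outdir / "expression_true.csv"
    write_expression(scenario.expression_true, paths["expression_true"])

    manifest = {
        "preset": scenario.preset,
        "seed": scenario.seed,
        "noise_sd": scenario.noise_sd,
        "scan_threshold": scenario.scan_threshold,
        "alpha": scenario.model_config.alpha,
        "window_mode": scenario.model_config.window_mode,
        "coactivation_variant": scenario.model_config.coactivation_variant,
        "reference_region": list(scenario.reference_region),
        "reference_nu": scenario.reference_nu,
        "origin_offset": off,
        "roles": dict(scenario.roles.roles),
        "coactivation": [list(e) for e in scenario.roles.coactivation],
        "cooperative": list(scenario.roles.cooperative),
        "true_params": dict(scenario.true_params),
        "planted": [list(p) for p in scenario.planted],
        "prior_range": {k: list(v) for k, v in scenario.prior_range.bounds.items()},
        "true_range": {k: list(v) for k, v in scenario.true_range.bounds.items()},
        "alt_params": dict(scenario.alt_params) if scenario.alt_params else None,
    }
    paths["manifest"] = outdir / "scenario.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def load_scenario(indir: str | Path) -> SyntheticScenario:
    """Reconstruct a scenario from a directory written by :func:`realize`."""
    from .io_formats import (
        read_expression,
        read_fasta,
        read_profiles,
        read_pwm,
        read_regions,
    )

    indir = Path(indir)
    with open(indir / "scenario.yaml") as fh:
        man = yaml.safe_load(fh)
    off = int(man["origin_offset"])
    closed = [(a, b) for a, b, _ in
              read_regions(indir / "closed_chromatin.bed", origin_offset=off)]
    locus = read_fasta(indir / "locus.fa", closed_regions=closed)
    roles = TFRoleTable(
        roles=dict(man["roles"]),
        coactivation=tuple(tuple(e) for e in man["coactivation"]),
        cooperative=tuple(man["cooperative"]),
    )
    pwms = tuple(read_pwm(indir / f"pwm_{tf}.jaspar") for tf in roles.tf_names)
    profiles = read_profiles(indir / "profiles.csv")
    expression = read_expression(indir / "expression.csv")
    expression_true = read_expression(indir / "expression_true.csv")
    return SyntheticScenario(
        preset=man["preset"], seed=int(man["seed"]), locus=locus, pwms=pwms,
        roles=roles, profiles=profiles,
        true_params=ParameterSet(man["true_params"]),
        noise_sd=float(man["noise_sd"]),
        scan_threshold=float(man["scan_threshold"]),
        model_config=ModelConfig(alpha=float(man["alpha"]),
                                 window_mode=man["window_mode"],
                                 coactivation_variant=man["coactivation_variant"]),
        reference_region=tuple(man["reference_region"]),
        reference_nu=float(man["reference_nu"]),
        planted=tuple((tf, int(p)) for tf, p in man["planted"]),
        expression_true=expression_true, expression=expression,
        prior_range=SearchRange({k: tuple(v) for k, v in man["prior_range"].items()}),
        true_range=SearchRange({k: tuple(v) for k, v in man["true_range"].items()}),
        alt_params=ParameterSet(man["alt_params"]) if man["alt_params"] else None,
    )
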