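"""Synthetic TPP datasets with known ground truth.

The generator emulates the structure of protein-level TPP experiments:
two conditions x two replicates over ten temperatures spanning 37-67 °C,
relative solubility near 1 at the lowest temperature and decaying with T.
Scenarios:

``null_sigmoid``
    identical sigmoid in both conditions (no treatment effect);
``shifted_sigmoid``
    treatment shifts the melting midpoint Tm = a/b by 2-5 °C (random sign)
    via a joint (a, b) perturbation — the canonical ligand-binding responder;
``gp_deviation``
    a smooth GP-distributed deviation added to the sigmoid, the same
    realization in both conditions (non-sigmoid but unaffected);
``biphasic``
    a fixed Gaussian bump added to the sigmoid in both conditions,
    mimicking two protein sub-populations melting at different points;
``biphasic_shifted``
    the bump plus a midpoint shift in the treatment condition (a responder
    that violates the sigmoid shape);
``hypersolubilised``
    a rising ramp added to the sigmoid, emulating proteins whose apparent
    solubility increases with temperature.

Replicates share one deviation realization per condition; only the
measurement noise is replicate-specific.  Values are truncated at zero
(relative solubility cannot be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ProteinMeltingData, TPPDataset
from .sigmoid import sigmoid

SCENARIOS = ("null_sigmoid", "shifted_sigmoid", "gp_deviation", "biphasic",
             "biphasic_shifted", "hypersolubilised")
AFFECTED_SCENARIOS = ("shifted_sigmoid", "biphasic_shifted")


@dataclass(frozen=True)
class Design:
    temperatures: tuple[float, ...] = tuple(np.linspace(37.0, 67.0, 10))
    conditions: tuple[str, str] = ("control", "treatment")
    n_replicates: int = 2


@dataclass(frozen=True)
class EffectSizes:
    """Ground-truth parameter ranges for the generator.

    Sigmoid truths are drawn so that melting midpoints (Tm = a/b) land in
    the 44-58 °C range with plateaus below 0.2, matching typical protein
    behaviour; the treatment shift of 2-5 °C is the size of thermal-shift
    effect the benchmark is meant to detect.
    """

    a_range: tuple[float, float] = (400.0, 900.0)
    tm_range: tuple[float, float] = (44.0, 58.0)
    p_range: tuple[float, float] = (0.0, 0.2)
    sigma_choices: tuple[float, ...] = (0.03, 0.08)
    tm_shift_range: tuple[float, float] = (2.0, 5.0)
    bump_amplitude_range: tuple[float, float] = (0.15, 0.3)
    bump_center_range: tuple[float, float] = (46.0, 54.0)
    bump_width_range: tuple[float, float] = (2.5, 4.0)
    ramp_amplitude_range: tuple[float, float] = (0.2, 0.5)
    gp_v: float = 0.1
    gp_l: float = 5.0


@dataclass
class SimulationTruth:
    """Ground truth for one simulated protein."""

    protein_id: str
    scenario: str
    treatment_affected: bool
    params: dict[str, dict[str, float]]            # condition -> {a, b, p, sigma}
    templates: dict[str, np.ndarray] = field(default_factory=dict)  # condition -> deviation
    tm_shift: float = 0.0
    gp_hyper: tuple[float, float] | None = None


def _uniform(rng, lo_hi):
    return float(rng.uniform(*lo_hi))


def _draw_truth(pid: str, scenario: str, design: Design, eff: EffectSizes,
                rng: np.random.Generator) -> SimulationTruth:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    T = np.asarray(design.temperatures)
    a = _uniform(rng, eff.a_range)
    tm = _uniform(rng, eff.tm_range)
    b = a / tm
    p = _uniform(rng, eff.p_range)
    sigma = float(rng.choice(eff.sigma_choices))
    ctrl, treat = design.conditions
    base = {"a": a, "b": b, "p": p, "sigma": sigma}
    params = {ctrl: dict(base), treat: dict(base)}
    templates: dict[str, np.ndarray] = {c: np.zeros(T.size) for c in design.conditions}
    tm_shift, gp_hyper = 0.0, None

    if scenario in ("shifted_sigmoid", "biphasic_shifted"):
        tm_shift = _uniform(rng, eff.tm_shift_range) * (1 if rng.random() < 0.5 else -1)
        params[treat]["b"] = a / (tm + tm_shift)
    if scenario in ("biphasic", "biphasic_shifted"):
        amp = _uniform(rng, eff.bump_amplitude_range)
        center = _uniform(rng, eff.bump_center_range)
        width = _uniform(rng, eff.bump_width_range)
        bump = amp * np.exp(-((T - center) ** 2) / (2.0 * width**2))
        for c in design.conditions:
            templates[c] = bump.copy()
    elif scenario == "hypersolubilised":
        amp = _uniform(rng, eff.ramp_amplitude_range)
        ramp = amp * (T - T.min()) / (T.max() - T.min())
        for c in design.conditions:
            templates[c] = ramp.copy()
    elif scenario == "gp_deviation":
        gp_hyper = (eff.gp_v, eff.gp_l)
        d2 = (T[:, None] - T[None, :]) ** 2
        C = eff.gp_v**2 * np.exp(-d2 / (2.0 * eff.gp_l**2)) + 1e-12 * np.eye(T.size)
        mu = np.linalg.cholesky(C) @ rng.standard_normal(T.size)
        for c in design.conditions:
            templates[c] = mu.copy()

    affected = scenario in AFFECTED_SCENARIOS
    return SimulationTruth(pid, scenario, affected, params, templates, tm_shift, gp_hyper)


def simulate_protein(truth: SimulationTruth, design: Design,
                     seed) -> ProteinMeltingData:
    """Observations y = S_{a,b,p}(T) + deviation(T) + N(0, sigma^2).

    The deviation template (bump/ramp/GP draw) is shared by all replicates
    of a condition; noise is i.i.d. per measurement.  Reproducible under a
    fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = np.asarray(design.temperatures)
    obs = {}
    for cond in design.conditions:
        prm = truth.params[cond]
        if prm["sigma"] < 0:
            raise ValueError("sigma must be >= 0")
        curve = sigmoid(T, prm["a"], prm["b"], prm["p"]) + truth.templates[cond]
        for k in range(1, design.n_replicates + 1):
            y = curve + rng.normal(0.0, prm["sigma"], size=T.size) if prm["sigma"] > 0 else curve.copy()
            obs[(cond, k)] = np.clip(y, 0.0, None)
    return ProteinMeltingData(truth.protein_id, T, design.conditions, obs)


def truth_table(truths: list[SimulationTruth], design: Design) -> pd.DataFrame:
    ctrl, treat = design.conditions
    rows = []
    for t in truths:
        rows.append({
            "protein_id": t.protein_id,
            "scenario": t.scenario,
            "treatment_affected": t.treatment_affected,
            "a_control": t.params[ctrl]["a"], "b_control": t.params[ctrl]["b"],
            "p_control": t.params[ctrl]["p"],
            "a_treatment": t.params[treat]["a"], "b_treatment": t.params[treat]["b"],
            "p_treatment": t.params[treat]["p"],
            "sigma": t.params[ctrl]["sigma"],
            "tm_shift": t.tm_shift,
        })
    return pd.DataFrame(rows)


def simulate_benchmark(scenario_counts: dict[str, int],
                       effect_sizes: EffectSizes | None = None,
                       design: Design | None = None,
                       seed: int = 0) -> tuple[TPPDataset, pd.DataFrame]:
    """Simulate a dataset with exact per-scenario protein counts.

    Unlike :func:`simulate_dataset`, which draws each protein's scenario from
    a mixture, this fixes the composition — the right tool for benchmarks
    whose sensitivity is computed against a known number of responders.
    """
    design = design or Design()
    eff = effect_sizes or EffectSizes()
    for name in scenario_counts:
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
    rng = np.random.default_rng(seed)
    n_total = sum(scenario_counts.values())
    width = len(str(max(n_total, 1)))
    proteins, truths = {}, []
    i = 0
    for scenario, count in scenario_counts.items():
        for _ in range(count):
            i += 1
            pid = f"P{i:0{width}d}"
            truth = _draw_truth(pid, scenario, design, eff, rng)
            proteins[pid] = simulate_protein(truth, design, rng)
            truths.append(truth)
    ds = TPPDataset(proteins=proteins, metadata={"simulated": True, "seed": seed})
    return ds, truth_table(truths, design)


def simulate_dataset(n_proteins: int, scenario_mix: dict[str, float],
                     effect_sizes: EffectSizes | None = None,
                     design: Design | None = None,
                     seed: int = 0) -> tuple[TPPDataset, pd.DataFrame]:
    """Simulate a full dataset; returns the dataset and its ground-truth table.

    ``scenario_mix`` maps scenario names to proportions summing to 1; each
    protein's scenario is drawn independently from the mix.
    """
    design = design or Design()
    eff = effect_sizes or EffectSizes()
    names = list(scenario_mix)
    probs = np.array([scenario_mix[n] for n in names], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("scenario mix proportions must be >= 0 and sum to 1")
    for n in names:
        if n not in SCENARIOS:
            raise ValueError(f"unknown scenario {n!r}")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_proteins, 1)))
    proteins, truths = {}, []
    for i in range(n_proteins):
        scenario = names[int(rng.choice(len(names), p=probs))]
        pid = f"P{i + 1:0{width}d}"
        truth = _draw_truth(pid, scenario, design, eff, rng)
        proteins[pid] = simulate_protein(truth, design, rng)
        truths.append(truth)
    ds = TPPDataset(proteins=proteins, metadata={"simulated": True, "seed": seed})
    return ds, truth_table(truths, design)
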