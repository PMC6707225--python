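"""Synthetic stopped-flow data: mass-action simulation of ligand binding.

Generates the raw material of a rapid-kinetics experiment — time courses of
the conformational-selection scheme (and of the competing induced-fit
scheme, for mechanism discrimination) observed through a weighted
fluorescence signal with instrument dead time, Gaussian noise and replicate
averaging.

The integrator solves the full second-order mass-action equations; no
pseudo-first-order approximation is made, so both the excess-ligand
titrations and the excess-macromolecule diagnostic come from the same
machinery.  Every titration is emitted together with a ground-truth record
of the parameters that generated it, for parameter-recovery studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import ArrheniusParameterSet, RateConstants, cs_relaxations

__all__ = [
    "DEFAULT_OBSERVABLE_WEIGHTS",
    "BINDING_OBSERVABLE_WEIGHTS",
    "TraceConfig",
    "Trace",
    "TitrationDesign",
    "InducedFitRateConstants",
    "simulate_scheme",
    "simulate_induced_fit",
    "render_trace",
    "simulate_titration",
    "default_time_grid",
    "write_trace",
    "read_trace",
    "write_titration",
    "read_titration",
]

#: Default signal coefficients per species: the closed E* conformation is
#: spectroscopically distinct while open protein and complex are equal, so
#: the signal tracks the conformational population and the fast binding
#: relaxation is silent — the regime observed for PPACK binding to
#: thrombin, where only the slow relaxation is detectable.  Sign/ordering
#: of the weights is irrelevant to rate extraction.
DEFAULT_OBSERVABLE_WEIGHTS: dict[str, float] = {"E_star": 1.6, "E": 1.0, "C": 1.0}

#: Binding-sensitive observable: the complex is the brightest species, both
#: relaxations carry amplitude.  Used automatically for frozen-conformation
#: (lock-and-key) variants, whose only kinetic signal is binding itself.
BINDING_OBSERVABLE_WEIGHTS: dict[str, float] = {"E_star": 1.0, "E": 1.0, "C": 1.6}

_CS_SPECIES = ("E_star", "E", "C")
_IF_SPECIES = ("E", "C1", "C2")


@dataclass(frozen=True)
class TraceConfig:
    """Instrument/observation model for rendering species courses into traces.

    Parameters
    ----------
    time_grid : array or None
        Sampling times in seconds (strictly increasing).  ``None`` lets the
        titration driver build a logarithmic grid scaled to the expected
        slow relaxation at each design point.
    dead_time : float
        Mixing dead time in seconds; points before it are discarded.
    noise_fraction : float
        Gaussian noise s.d. as a fraction of the noise-free dynamic range.
    n_replicates : int
        Number of replicate shots averaged into one recorded trace.
    seed : int
        Base seed; each trace of a titration derives its own stream.
    observable_weights : dict
        Signal coefficient per species name.
    """

    time_grid: np.ndarray | None = None
    dead_time: float = 1e-3
    noise_fraction: float = 0.05
    n_replicates: int = 10
    seed: int = 0
    observable_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OBSERVABLE_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.time_grid is not None:
            grid = np.asarray(self.time_grid, dtype=float)
            if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError("time_grid must be strictly increasing, length >= 2")
            object.__setattr__(self, "time_grid", grid)


@dataclass(frozen=True)
class Trace:
    """One recorded stopped-flow time course (replicate-averaged)."""

    times: np.ndarray
    signal: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        if len(self.times) != len(self.signal):
            raise ValueError("times and signal must have the same length")


@dataclass(frozen=True)
class TitrationDesign:
    """Design of a titration: ligand/protein concentrations and temperatures.

    ``regime`` encodes which reactant is in pseudo-first-order excess:
    ``excess_ligand`` (classic titration, [L]/[P] >= 10 at every point) or
    ``excess_macromolecule`` (the conformational-selection diagnostic,
    [P]/[L] >= 10 at every point).
    """

    ligand_concentrations: tuple[float, ...]
    protein_concentration: float | tuple[float, ...]
    temperatures: tuple[float, ...] = (288.15,)
    regime: Literal["excess_ligand", "excess_macromolecule"] = "excess_ligand"

    def __post_init__(self) -> None:
        ligands = tuple(float(v) for v in np.atleast_1d(self.ligand_concentrations))
        proteins = tuple(float(v) for v in np.atleast_1d(self.protein_concentration))
        temps = tuple(float(v) for v in np.atleast_1d(self.temperatures))
        object.__setattr__(self, "ligand_concentrations", ligands)
        object.__setattr__(self, "protein_concentration", proteins)
        object.__setattr__(self, "temperatures", temps)
        if any(v < 0 for v in ligands) or any(v <= 0 for v in proteins):
            raise ValueError("concentrations must be non-negative (protein positive)")
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive (kelvin)")
        for ligand, protein in self.points():
            if self.regime == "excess_ligand":
                if ligand > 0 and ligand / protein < 10:
                    raise ValueError(
                        f"excess_ligand regime requires [L]/[P] >= 10; "
                        f"got L={ligand}, P={protein}"
                    )
            else:
                if ligand > 0 and protein / ligand < 10:
                    raise ValueError(
                        f"excess_macromolecule regime requires [P]/[L] >= 10; "
                        f"got L={ligand}, P={protein}"
                    )

    def points(self) -> list[tuple[float, float]]:
        """(ligand, protein) pairs: the varied axis is paired with the fixed one."""
        ligands = self.ligand_concentrations
        proteins = self.protein_concentration
        if len(proteins) == 1:
            return [(lig, proteins[0]) for lig in ligands]
        if len(ligands) == 1:
            return [(ligands[0], prot) for prot in proteins]
        if len(ligands) == len(proteins):
            return list(zip(ligands, proteins))
        raise ValueError("ligand and protein lists must be broadcastable")


@dataclass(frozen=True)
class InducedFitRateConstants:
    """Two-step binding-then-isomerisation (induced fit) scheme:

        E + L  <-- kon/koff -->  C1  <-- kf/kr -->  C2

    kon in uM^-1 s^-1, the rest s^-1.  Used as the alternative model in
    mechanism discrimination; ligand binds a single protein conformation
    and the complex isomerises afterwards.
    """

    kon: float
    koff: float
    kf: float
    kr: float

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "kf", "kr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_time_grid(
    slow_rate: float, dead_time: float = 1e-3, n_points: int = 600
) -> np.ndarray:
    """Logarithmic grid from half the dead time to ~6 slow time constants.

    The span is clamped to [0.1, 100] s so degenerate rates still produce a
    usable window; 6 time constants leave >95% of the slow amplitude inside
    the record.
    """
    if slow_rate > 0:
        t_max = float(np.clip(6.0 / slow_rate, 0.1, 100.0))
    else:
        t_max = 1.0
    t_min = max(dead_time / 2.0, 1e-5)
    return np.geomspace(t_min, t_max, n_points)


def _integrate(rhs, jac, y0, time_grid, species: Sequence[str]) -> pd.DataFrame:
    t_span = (0.0, float(time_grid[-1]))
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="BDF",
        t_eval=np.asarray(time_grid, dtype=float),
        jac=jac,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"kinetic integration failed: {sol.message}")
    frame = pd.DataFrame({"time_s": sol.t})
    for i, name in enumerate(species):
        frame[name] = sol.y[i]
    return frame


def simulate_scheme(
    rc: RateConstants,
    ligand_uM: float,
    protein_uM: float,
    time_grid: np.ndarray,
) -> pd.DataFrame:
    """Integrate the conformational-selection scheme in full mass action.

    The free protein starts at its conformational pre-equilibrium
    (E*:E = k21:k12; all open if the exchange is frozen), with no complex;
    ligand is mixed in at t = 0.  Returns species concentrations (uM) on
    ``time_grid`` plus the free-ligand column; total protein and ligand are
    conserved by construction and the integration is run at rtol 1e-10.
    """
    if ligand_uM < 0 or protein_uM <= 0:
        raise ValueError("ligand must be >= 0 and protein > 0 (uM)")
    k12, k21, kon, koff = rc.k12, rc.k21, rc.kon, rc.koff
    ltot = float(ligand_uM)

    if rc.exchange_rate > 0:
        estar0 = protein_uM * rc.k21 / rc.exchange_rate
    else:
        estar0 = 0.0  # frozen single-conformation (lock-and-key) limit
    y0 = [estar0, protein_uM - estar0, 0.0]

    def rhs(_t, y):
        estar, e, c = y
        lfree = ltot - c
        bind = kon * e * lfree - koff * c
        return [
            -k12 * estar + k21 * e,
            k12 * estar - k21 * e - bind,
            bind,
        ]

    def jac(_t, y):
        _estar, e, c = y
        lfree = ltot - c
        return [
            [-k12, k21, 0.0],
            [k12, -k21 - kon * lfree, kon * e + koff],
            [0.0, kon * lfree, -kon * e - koff],
        ]

    frame = _integrate(rhs, jac, y0, time_grid, _CS_SPECIES)
    frame["L_free"] = ltot - frame["C"]
    return frame


def simulate_induced_fit(
    rc: InducedFitRateConstants,
    ligand_uM: float,
    protein_uM: float,
    time_grid: np.ndarray,
) -> pd.DataFrame:
    """Integrate the induced-fit scheme (binding first, then isomerisation)."""
    if ligand_uM < 0 or protein_uM <= 0:
        raise ValueError("ligand must be >= 0 and protein > 0 (uM)")
    kon, koff, kf, kr = rc.kon, rc.koff, rc.kf, rc.kr
    ltot = float(ligand_uM)
    y0 = [protein_uM, 0.0, 0.0]

    def rhs(_t, y):
        e, c1, c2 = y
        lfree = ltot - c1 - c2
        bind = kon * e * lfree - koff * c1
        iso = kf * c1 - kr * c2
        return [-bind, bind - iso, iso]

    def jac(_t, y):
        e, c1, c2 = y
        lfree = ltot - c1 - c2
        return [
            [-kon * lfree, kon * e + koff, kon * e],
            [kon * lfree, -kon * e - koff - kf, -kon * e + kr],
            [0.0, kf, -kr],
        ]

    frame = _integrate(rhs, jac, y0, time_grid, _IF_SPECIES)
    frame["L_free"] = ltot - frame["C1"] - frame["C2"]
    return frame


def render_trace(
    courses: pd.DataFrame,
    cfg: TraceConfig,
    metadata: dict | None = None,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Turn species courses into one recorded trace.

    signal(t) = sum_i w_i * species_i(t); points before the dead time are
    discarded; each replicate receives i.i.d. Gaussian noise with s.d. =
    ``noise_fraction`` x (noise-free dynamic range) and the replicates are
    averaged.  Deterministic for a fixed seed.
    """
    times = courses["time_s"].to_numpy()
    keep = times >= cfg.dead_time
    if not np.any(keep):
        raise ValueError("no sampling points survive the dead time")
    times = times[keep]
    clean = np.zeros(times.shape)
    for species, weight in cfg.observable_weights.items():
        if species in courses:
            clean = clean + weight * courses[species].to_numpy()[keep]
    if cfg.noise_fraction == 0:
        signal = clean
    else:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        span = float(np.ptp(clean))
        sd = cfg.noise_fraction * (span if span > 0 else 1.0)
        reps = clean[None, :] + rng.normal(0.0, sd, size=(cfg.n_replicates, clean.size))
        signal = reps.mean(axis=0)
    meta = dict(metadata or {})
    meta.setdefault("n_replicates", cfg.n_replicates)
    meta.setdefault("noise_fraction", cfg.noise_fraction)
    meta.setdefault("dead_time_s", cfg.dead_time)
    return Trace(times=times, signal=signal, metadata=meta)


def _expected_slow_rate(
    rc: RateConstants, ligand: float, protein: float, regime: str
) -> float:
    """Slow relaxation used only to scale the sampling window."""
    if regime == "excess_macromolecule":
        f_open = rc.fraction_open if rc.exchange_rate > 0 else 1.0
        return rc.koff + rc.kon * f_open * protein
    pair = cs_relaxations(rc, ligand)
    if pair.alpha2 > 0:
        return pair.alpha2
    return pair.alpha1  # frozen-conformation limit: single binding relaxation


def simulate_titration(
    params: RateConstants | ArrheniusParameterSet,
    design: TitrationDesign,
    cfg: TraceConfig,
) -> tuple[list[Trace], dict]:
    """Simulate one averaged trace per (ligand/protein point, temperature).

    For a temperature series the rate constants are evaluated from the
    Arrhenius law at each temperature.  Returns the traces plus a
    ground-truth record of every parameter used (for recovery tests).
    Noise streams are spawned per trace from ``cfg.seed`` so the whole
    titration is reproducible and traces are mutually independent.
    """
    traces: list[Trace] = []
    truth_points = []
    streams = np.random.SeedSequence(cfg.seed).spawn(
        len(design.temperatures) * len(design.points())
    )
    idx = 0
    for temperature in design.temperatures:
        if isinstance(params, ArrheniusParameterSet):
            rc = params.at_temperature(temperature)
        else:
            rc = params
        # the conformational observable is blind to pure binding: frozen
        # variants and the excess-macromolecule diagnostic are recorded
        # through the binding-sensitive observable instead
        point_cfg = cfg
        if cfg.observable_weights == DEFAULT_OBSERVABLE_WEIGHTS and (
            rc.exchange_rate == 0 or design.regime == "excess_macromolecule"
        ):
            point_cfg = dataclasses.replace(
                cfg, observable_weights=dict(BINDING_OBSERVABLE_WEIGHTS)
            )
        for ligand, protein in design.points():
            slow = _expected_slow_rate(rc, ligand, protein, design.regime)
            grid = (
                cfg.time_grid
                if cfg.time_grid is not None
                else default_time_grid(slow, cfg.dead_time)
            )
            courses = simulate_scheme(rc, ligand, protein, grid)
            pair = cs_relaxations(rc, ligand)
            meta = {
                "ligand_uM": ligand,
                "protein_uM": protein,
                "temperature_K": temperature,
                "regime": design.regime,
            }
            rng = np.random.default_rng(streams[idx])
            traces.append(render_trace(courses, point_cfg, meta, rng=rng))
            truth_points.append(
                {
                    **meta,
                    "k12": rc.k12,
                    "k21": rc.k21,
                    "kon": rc.kon,
                    "koff": rc.koff,
                    "alpha1": pair.alpha1,
                    "alpha2": pair.alpha2,
                }
            )
            idx += 1
    truth = {
        "seed": cfg.seed,
        "regime": design.regime,
        "noise_fraction": cfg.noise_fraction,
        "n_replicates": cfg.n_replicates,
        "dead_time_s": cfg.dead_time,
        "parameters": (
            dataclasses.asdict(params)
            if isinstance(params, (RateConstants, ArrheniusParameterSet))
            else params
        ),
        "points": truth_points,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# Plain-text I/O: one 2-column TSV per trace plus a JSON metadata sidecar;
# titrations as a directory with a manifest.


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "signal": trace.signal}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(trace.metadata, indent=1, sort_keys=True))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two delimited columns (time, signal)")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trace(
        times=frame.iloc[:, 0].to_numpy(float),
        signal=frame.iloc[:, 1].to_numpy(float),
        metadata=meta,
    )


def write_titration(
    traces: Iterable[Trace], truth: dict, directory: str | Path
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, trace in enumerate(traces):
        name = f"trace_{i:03d}.tsv"
        write_trace(trace, directory / name)
        names.append(name)
    manifest = {"traces": names, "ground_truth": truth}
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_titration(directory: str | Path) -> tuple[list[Trace], dict]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    traces = [read_trace(directory / name) for name in manifest["traces"]]
    return traces, manifest.get("ground_truth", {})
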