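"""Scenario configuration, presets and file outputs.

A :class:`Scenario` bundles everything one simulation arm needs —
structure, parameters, initial placement, replicate count and seed — and
can be loaded from a flat JSON config.  Presets encode the
parameterizations of the standard study designs (deme-structured serial
passage on a star or clique, with a well-mixed reference) at full scale;
a ``scale`` factor multiplies replicate counts for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .ensemble import summarize
from .graphs import MigrationGraph, build_clique, build_star, build_well_mixed, read_matrix_tsv
from .hard_selection import HardSelectionParams, run_ensemble_hard
from .simulate import (
    EnsembleResult,
    PopulationParams,
    make_initial_state,
    run_ensemble,
)
from .theory import wilson_interval

__all__ = ["Scenario", "load_config", "run_scenario", "preset", "PRESET_NAMES"]

_STRUCTURES = ("wellmixed", "clique", "star", "custom")
_SELECTIONS = ("soft", "hard")


@dataclass
class Scenario:
    """One fully resolved simulation arm."""

    name: str
    structure: str
    B: float
    reps: int
    seed: int
    D: int = 1
    st: float | None = None
    s: float | None = None
    t: float = math.log(100.0)
    m: float | None = None
    m_I: float | None = None
    alpha: float | None = None
    convention: str = "receive_B"
    placement: str = "uniform"
    max_steps: int = 10**6
    selection: str = "soft"
    d: float | None = None
    K_wt: float | None = None
    density_ratio: float = 1.4
    record_fractions: bool = True
    matrix_path: str | None = None

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; expected one of {_STRUCTURES}")
        if self.selection not in _SELECTIONS:
            raise ValueError(f"unknown selection {self.selection!r}; expected one of {_SELECTIONS}")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.selection == "hard" and (self.d is None or self.K_wt is None):
            raise ValueError("hard selection requires the dilution factor d and capacity K_wt")

    def graph(self) -> MigrationGraph:
        if self.structure == "wellmixed":
            return build_well_mixed(int(self.B), self.convention)
        if self.structure == "clique":
            if self.m is None:
                raise ValueError("clique scenario requires the migration probability m")
            return build_clique(self.D, self.m, self.convention)
        if self.structure == "star":
            if self.m_I is None or self.alpha is None:
                raise ValueError("star scenario requires m_I and alpha")
            return build_star(self.D, self.m_I, self.alpha, self.convention)
        if self.matrix_path is None:
            raise ValueError("custom scenario requires matrix_path")
        return read_matrix_tsv(self.matrix_path, self.convention)

    def params(self) -> PopulationParams:
        return PopulationParams(B=self.B, st=self.st, s=self.s, t=self.t, max_steps=self.max_steps)

    def hard_params(self) -> HardSelectionParams:
        params = self.params()  # resolves s from st if needed
        return HardSelectionParams(
            d=self.d,
            K_wt=self.K_wt,
            s=params.s,
            t=self.t,
            density_ratio=self.density_ratio,
            max_steps=self.max_steps,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "Scenario":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        required = {"name", "structure", "B", "reps", "seed"}
        missing = required - set(raw)
        if missing:
            raise ValueError(f"missing required scenario keys: {sorted(missing)}")
        return cls(**raw)


def load_config(path: str | Path) -> Scenario:
    """Load and validate a Scenario from a flat JSON document."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a JSON object")
    return Scenario.from_dict(raw)


def run_scenario(sc: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Run one scenario arm and write its outputs.

    Writes ``<name>_summary.tsv`` (one row of ensemble statistics with
    Wilson bounds on the fixation proportion), ``<name>_trajectories.tsv``
    (tidy per-step overall fractions, if recorded) and
    ``<name>_manifest.json`` echoing every resolved parameter.  Outputs
    are deterministic given the seed; partial files are removed if the
    run fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": outdir / f"{sc.name}_summary.tsv",
        "trajectories": outdir / f"{sc.name}_trajectories.tsv",
        "manifest": outdir / f"{sc.name}_manifest.json",
    }
    try:
        g = sc.graph()
        rng = np.random.default_rng(sc.seed)
        if sc.selection == "soft":
            res = run_ensemble(g, sc.params(), sc.placement, sc.reps, rng, sc.record_fractions)
        else:
            init = make_initial_state(g, sc.params(), sc.placement, rng)
            res = run_ensemble_hard(g, sc.hard_params(), init, sc.reps, rng, sc.record_fractions)
        _write_summary(sc, res, paths["summary"])
        if sc.record_fractions:
            _write_trajectories(res, paths["trajectories"])
        else:
            paths.pop("trajectories")
        manifest = {"scenario": sc.to_dict(), "version": _version}
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception:
        for p in paths.values():
            p.unlink(missing_ok=True)
        raise
    return paths


def _write_summary(sc: Scenario, res: EnsembleResult, path: Path) -> None:
    s = summarize(res)
    row = dataclasses.asdict(s)
    iqr_f = row.pop("fix_time_iqr")
    iqr_e = row.pop("ext_time_iqr")
    row["fix_time_q25"], row["fix_time_q75"] = iqr_f
    row["ext_time_q25"], row["ext_time_q75"] = iqr_e
    resolved = s.n_fixed + s.n_extinct
    if resolved:
        ci = wilson_interval(s.rho_hat, resolved)
        row["rho_wilson_lower"], row["rho_wilson_upper"] = ci.lower, ci.upper
    row = {"scenario": sc.name, **row}
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def _write_trajectories(res: EnsembleResult, path: Path) -> None:
    frames = []
    for tid, traj in enumerate(res.trajectories()):
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": tid,
                    "step": np.arange(traj.fractions.size),
                    "overall_fraction": traj.fractions,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# presets

_FIG2_COMMON = dict(
    D=4,
    B=1e7,
    s=0.2,
    t=math.log(100.0),
    convention="contribute_B",
    max_steps=10**4,
)
_FIG2_M_GRID = (0.3, 0.01, 1e-5)

_STAR5 = dict(structure="star", D=5, B=100, m_I=0.05, convention="receive_B", st=0.01)


def _fig2(scale: float, seed: int) -> list[Scenario]:
    """Mutant-fraction growth, D=4, B=1e7, st = 0.2 ln(100).

    One deme starts with 1e4 mutants (initial overall fraction 2.5e-4);
    star asymmetry alpha = 3 with m_O swept over the migration grid, the
    clique swept over the same m, plus a well-mixed DB = 4e7 reference.
    """
    reps = max(1, round(100 * scale))
    arms = []
    for m in _FIG2_M_GRID:
        for tag, placement in (("center", "count:10000:0"), ("leaf", "count:10000:1")):
            arms.append(
                Scenario(
                    name=f"fig2_star_{tag}_m{m:g}",
                    structure="star",
                    m_I=3 * m,
                    alpha=3.0,
                    placement=placement,
                    reps=reps,
                    seed=seed,
                    **_FIG2_COMMON,
                )
            )
        arms.append(
            Scenario(
                name=f"fig2_clique_m{m:g}",
                structure="clique",
                m=m,
                placement="count:10000:0",
                reps=reps,
                seed=seed,
                **_FIG2_COMMON,
            )
        )
    arms.append(
        Scenario(
            name="fig2_wellmixed",
            structure="wellmixed",
            B=4e7,
            s=0.2,
            t=math.log(100.0),
            placement="count:10000",
            reps=reps,
            seed=seed,
            max_steps=10**4,
        )
    )
    return arms


def _fig3(scale: float, seed: int) -> list[Scenario]:
    """Fixation probability and times vs st; star alpha sweep at m_I=0.05."""
    reps = max(1, round(100_000 * scale))
    st_grid = (0.001, 0.0025, 0.005, 0.01, 0.025, 0.05)
    arms = []
    for st in st_grid:
        for alpha in (0.1, 1 / 3, 1.0, 3.0):
            arms.append(
                Scenario(
                    name=f"fig3_star_a{alpha:g}_st{st:g}",
                    structure="star",
                    D=5,
                    B=100,
                    m_I=0.05,
                    alpha=alpha,
                    convention="receive_B",
                    st=st,
                    placement="uniform",
                    reps=reps,
                    seed=seed,
                    record_fractions=False,
                )
            )
        arms.append(
            Scenario(
                name=f"fig3_clique_st{st:g}",
                structure="clique",
                D=5,
                B=100,
                m=0.02,
                st=st,
                placement="uniform",
                reps=reps,
                seed=seed,
                record_fractions=False,
            )
        )
        arms.append(
            Scenario(
                name=f"fig3_wellmixed_st{st:g}",
                structure="wellmixed",
                B=500,
                st=st,
                placement="count:100",
                reps=reps,
                seed=seed,
                record_fractions=False,
            )
        )
    return arms


def _fig45_arms(reps_star: int, reps_clique: int, seed: int, record: bool) -> list[Scenario]:
    arms = [
        Scenario(
            name=f"fig_star_{tag}",
            placement=placement,
            alpha=0.1,
            reps=reps_star,
            seed=seed,
            record_fractions=record,
            **_STAR5,
        )
        for tag, placement in (("center", "center"), ("leaf", "leaf"), ("any", "uniform"))
    ]
    arms.append(
        Scenario(
            name="fig_clique",
            structure="clique",
            D=5,
            B=100,
            m=0.11,
            st=0.01,
            placement="uniform",
            reps=reps_clique,
            seed=seed,
            record_fractions=record,
        )
    )
    arms.append(
        Scenario(
            name="fig_wellmixed",
            structure="wellmixed",
            B=500,
            st=0.01,
            placement="count:100",
            reps=reps_clique,
            seed=seed,
            record_fractions=record,
        )
    )
    return arms


def _fig4(scale: float, seed: int) -> list[Scenario]:
    """Fixation/extinction time distributions at st=0.01, m_I=0.05, alpha=1/10."""
    reps = max(1, round(25_000 * scale))
    return _fig45_arms(reps, reps, seed, record=False)


def _fig5(scale: float, seed: int) -> list[Scenario]:
    """Average mutant-fraction trajectories for the fig4 arms (fractions kept)."""
    reps = max(1, round(5_000 * scale))
    return _fig45_arms(reps, max(1, round(6_000 * scale)), seed, record=True)


def _s1(scale: float, seed: int) -> list[Scenario]:
    """Hard-selection variant of the fig2 design: logistic growth to
    capacity K_wt = d B with d = 100, growth time long enough to saturate
    (t = 2 ln 100), 40% post-growth density difference."""
    reps = max(1, round(100 * scale))
    t = 2 * math.log(100.0)
    arms = []
    for m in _FIG2_M_GRID:
        arms.append(
            Scenario(
                name=f"s1_star_leaf_m{m:g}",
                structure="star",
                D=4,
                B=1e7,
                m_I=3 * m,
                alpha=3.0,
                convention="contribute_B",
                s=0.2,
                t=t,
                placement="count:10000:1",
                reps=reps,
                seed=seed,
                selection="hard",
                d=100.0,
                K_wt=1e9,
                density_ratio=1.4,
                max_steps=10**4,
            )
        )
        arms.append(
            Scenario(
                name=f"s1_clique_m{m:g}",
                structure="clique",
                D=4,
                B=1e7,
                m=m,
                convention="contribute_B",
                s=0.2,
                t=t,
                placement="count:10000:0",
                reps=reps,
                seed=seed,
                selection="hard",
                d=100.0,
                K_wt=1e9,
                density_ratio=1.4,
                max_steps=10**4,
            )
        )
    return arms


_PRESETS = {"fig2": _fig2, "fig3": _fig3, "fig4": _fig4, "fig5": _fig5, "s1": _s1}
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, scale: float = 1.0, seed: int = 0) -> list[Scenario]:
    """Scenario arms of a named preset, with replicate counts scaled."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    return _PRESETS[name](scale, seed)
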