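"""Canned experiment presets and their batch runner.

The four presets mirror the study's simulation campaigns:

``ba_ba``      two BA(500, m=2) layers, all three dominance modes,
               r in {0.2, 0.5, 0.8}, initial fractions (0.5, 0.5)
``ba_ws``      BA(500, m=2) over WS(500, k=4, p=0.5), same modes/r,
               initial fractions (0.5, 0.3)
``ba_ws_ba``   BA-WS-BA three-layer stack, same modes/r,
               initial fractions (0.5, 0.3, 0.5)
``ws_rsweep``  the BA-WS-BA stack under defection dominance only, swept
               over r = 0.1 .. 0.8 in steps of 0.1; the WS layer is the
               one of interest

Common conditions: N = 500 per layer, kappa = 0.1, 1000 synchronous
rounds, 20 replicates with fresh networks, stationary window = last 200
steps.
"""

from __future__ import annotations

import json
import os
import platform
import sys
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .game import DominanceMode
from .networks import LayerSpec
from .simulate import SimulationConfig, summarize, run_replicates

__all__ = ["ExperimentPreset", "PRESETS", "run_preset", "compare_modes"]

N_NODES = 500
BA_M = 2
WS_K = 4
WS_P = 0.5
F_BA = 0.5
F_WS = 0.3

_BA = LayerSpec.ba(N_NODES, BA_M)
_WS = LayerSpec.ws(N_NODES, WS_K, WS_P)

ALL_MODES = (DominanceMode.NATURAL, DominanceMode.COOP, DominanceMode.DEFECT)


@dataclass(frozen=True)
class ExperimentPreset:
    """A fully specified experiment: layers, modes, r grid and defaults."""

    name: str
    layer_specs: tuple[LayerSpec, ...]
    layer_names: tuple[str, ...]
    modes: tuple[DominanceMode, ...]
    r_values: tuple[float, ...]
    initial_fractions: tuple[float, ...]

    def base_config(self, **overrides) -> SimulationConfig:
        kwargs = dict(
            r=self.r_values[0],
            initial_fractions=self.initial_fractions,
        )
        kwargs.update(overrides)
        return SimulationConfig(**kwargs)


PRESETS: dict[str, ExperimentPreset] = {
    "ba_ba": ExperimentPreset(
        name="ba_ba",
        layer_specs=(_BA, _BA),
        layer_names=("BA1", "BA2"),
        modes=ALL_MODES,
        r_values=(0.2, 0.5, 0.8),
        initial_fractions=(F_BA, F_BA),
    ),
    "ba_ws": ExperimentPreset(
        name="ba_ws",
        layer_specs=(_BA, _WS),
        layer_names=("BA1", "WS2"),
        modes=ALL_MODES,
        r_values=(0.2, 0.5, 0.8),
        initial_fractions=(F_BA, F_WS),
    ),
    "ba_ws_ba": ExperimentPreset(
        name="ba_ws_ba",
        layer_specs=(_BA, _WS, _BA),
        layer_names=("BA1", "WS2", "BA3"),
        modes=ALL_MODES,
        r_values=(0.2, 0.5, 0.8),
        initial_fractions=(F_BA, F_WS, F_BA),
    ),
    "ws_rsweep": ExperimentPreset(
        name="ws_rsweep",
        layer_specs=(_BA, _WS, _BA),
        layer_names=("BA1", "WS2", "BA3"),
        modes=(DominanceMode.DEFECT,),
        r_values=tuple(np.round(np.arange(0.1, 0.85, 0.1), 1)),
        initial_fractions=(F_BA, F_WS, F_BA),
    ),
}


def _atomic_write(path: Path, text: str) -> None:
    """Write via a temp file + rename so a crash never leaves a torn file."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def run_preset(
    preset_name: str,
    output_dir,
    seed: int = 0,
    overrides: Mapping | None = None,
    make_plots: bool = True,
    log=None,
) -> dict:
    """Run one preset end to end and write its result files.

    Produces, under ``output_dir / preset_name``:

    - ``config.json`` — the resolved configuration, seed and versions
    - ``trajectories_<mode>_r<r>.csv`` — long-format per-replicate series
      (columns replicate, step, layer, fraction)
    - ``summary.csv`` / ``summary.json`` — pooled stationary summaries for
      every (mode, r, layer)
    - one trajectory plot per (mode, r) when ``make_plots``

    Every file regenerates bit-identically from the same seed.  Returns the
    summary table (also handy for tests) as a dict with the DataFrame under
    "summary".
    """
    if preset_name not in PRESETS:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    preset = PRESETS[preset_name]
    overrides = dict(overrides or {})
    out = Path(output_dir) / preset.name
    out.mkdir(parents=True, exist_ok=True)
    log = log or (lambda msg: print(msg, file=sys.stderr))

    base = preset.base_config(seed=seed, **overrides)
    meta = {
        "preset": preset.name,
        "seed": seed,
        "layer_specs": [vars(s) for s in preset.layer_specs],
        "modes": [m.value for m in preset.modes],
        "r_values": list(preset.r_values),
        "config": {
            k: (v.value if isinstance(v, DominanceMode) else v)
            for k, v in vars(base).items()
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    _atomic_write(out / "config.json", json.dumps(meta, indent=2))

    summary_rows = []
    for mode in preset.modes:
        for r in preset.r_values:
            config = base.with_(mode=mode, r=float(r))
            log(f"[{preset.name}] mode={mode.value} r={r} seed={seed}")
            trajectories = run_replicates(preset.layer_specs, config)
            frame = pd.concat([t.to_dataframe() for t in trajectories])
            tag = f"{mode.value}_r{r:g}"
            _atomic_write(out / f"trajectories_{tag}.csv", frame.to_csv(index=False))
            stats = summarize(trajectories)
            for ell in range(len(stats.means)):
                summary_rows.append(
                    {
                        "mode": mode.value,
                        "r": float(r),
                        "layer": ell,
                        "layer_name": preset.layer_names[ell],
                        "mean": float(stats.means[ell]),
                        "sd": float(stats.sds[ell]),
                        "n_replicates": stats.n_replicates,
                        "window": stats.window,
                    }
                )
            if make_plots:
                from .plotting import plot_trajectories

                plot_trajectories(
                    trajectories,
                    path=out / f"trajectories_{tag}.png",
                    layer_names=preset.layer_names,
                    title=f"{preset.name}: {mode.value}, r={r:g}",
                )
    summary = pd.DataFrame(summary_rows)
    _atomic_write(out / "summary.csv", summary.to_csv(index=False))
    _atomic_write(
        out / "summary.json", json.dumps(summary.to_dict(orient="records"), indent=2)
    )
    if make_plots and preset.name == "ws_rsweep":
        from .plotting import plot_sweep

        sweep_view = summary.rename(columns={})
        plot_sweep(
            sweep_view, path=out / "sweep.png", layer_names=list(preset.layer_names)
        )
    return {"summary": summary, "output_dir": out, "meta": meta}


def compare_modes(
    summary: pd.DataFrame, baseline: str = DominanceMode.NATURAL.value
) -> pd.DataFrame:
    """Tabulate stationary means by mode and their difference from a baseline.

    Expects a summary table as produced by :func:`run_preset` covering at
    least two modes on the same (layer, r) grid.  Returns one row per
    (layer, r, mode != baseline) with the mean difference and a pooled
    replicate-based uncertainty (quadrature sum of the two sds).
    """
    modes = sorted(summary["mode"].unique())
    if len(modes) < 2:
        raise ValueError("need summaries for at least two modes")
    if baseline not in modes:
        baseline = modes[0]
    base = summary[summary["mode"] == baseline].set_index(["layer", "r"])
    rows = []
    for mode in modes:
        if mode == baseline:
            continue
        other = summary[summary["mode"] == mode].set_index(["layer", "r"])
        if not other.index.equals(base.index):
            raise ValueError(
                f"mode {mode!r} covers a different (layer, r) grid than "
                f"baseline {baseline!r}"
            )
        for key in base.index:
            layer, r = key
            rows.append(
                {
                    "layer": layer,
                    "r": r,
                    "mode": mode,
                    "baseline": baseline,
                    "mean": float(other.loc[key, "mean"]),
                    "baseline_mean": float(base.loc[key, "mean"]),
                    "difference": float(
                        other.loc[key, "mean"] - base.loc[key, "mean"]
                    ),
                    "uncertainty": float(
                        np.hypot(other.loc[key, "sd"], base.loc[key, "sd"])
                    ),
                }
            )
    return pd.DataFrame(rows).sort_values(["layer", "r", "mode"]).reset_index(drop=True)
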