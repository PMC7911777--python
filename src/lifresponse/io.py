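"""File formats: configs (YAML/JSON), sparse spike events (CSV), dense
rasters (npz), tidy traces and kernels (CSV).

Conventions: neuron and time indices are 0-based in every file format;
sparse event files have the header ``trial,neuron,time``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import NetworkParameters
from .simulate import TrialEnsemble
from .stats import ResponseTrace
from .topology import StimulusField, build_lattice_weights

__all__ = [
    "params_from_dict",
    "params_to_dict",
    "load_config",
    "stimulus_from_config",
    "ensemble_to_events",
    "events_to_ensemble",
    "save_ensemble_npz",
    "load_ensemble_npz",
    "trace_to_frame",
    "save_traces_csv",
    "kernel_to_frame",
    "save_stimulus_csv",
    "load_stimulus_csv",
]


def params_from_dict(cfg: dict) -> NetworkParameters:
    """Build parameters from a config mapping.

    Accepts either an explicit dense ``weights`` matrix or a
    ``lattice: {N, w_plus, w_minus}`` spec.
    """
    if "lattice" in cfg:
        lat = cfg["lattice"]
        n = int(lat["N"])
        weights = build_lattice_weights(n, float(lat["w_plus"]), float(lat["w_minus"]))
    else:
        weights = np.asarray(cfg["weights"], dtype=float)
        n = int(cfg.get("N", weights.shape[0]))
    return NetworkParameters(
        n_neurons=n, weights=weights, gamma=float(cfg["gamma"]),
        theta=float(cfg["theta"]), i0=float(cfg["I0"]),
        sigma_b=float(cfg["sigma_B"]),
    )


def params_to_dict(params: NetworkParameters) -> dict:
    return {
        "N": params.n_neurons,
        "gamma": params.gamma,
        "theta": params.theta,
        "I0": params.i0,
        "sigma_B": params.sigma_b,
        "weights": params.weights.tolist(),
    }


def load_config(path) -> dict:
    """Read a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def stimulus_from_config(cfg: dict, n_neurons: int, t_steps: int) -> StimulusField:
    """Build the moving Gaussian pulse from its config block."""
    from .topology import moving_gaussian_stimulus

    s = cfg["stimulus"]
    lat = cfg.get("lattice", {})
    return moving_gaussian_stimulus(
        amplitude=float(s["A"]), delta=float(s["Delta_mm"]),
        v=float(s["v_mm_per_s"]), dx=float(lat.get("dx_mm", 1.0)),
        b=float(s["b_ms"]) / 1000.0, n_neurons=n_neurons,
        t0=int(s["t0"]), n_steps=t_steps,
        x_start=float(s.get("x_start_mm", 0.0)),
    )


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def ensemble_to_events(ensemble: TrialEnsemble) -> pd.DataFrame:
    """Sparse event triplets (trial, neuron, time), 0-based, post-burn-in only."""
    lo, hi = ensemble.analysis_window()
    cols = slice(lo - ensemble.n_min, hi - ensemble.n_min + 1)
    trial, neuron, time = np.nonzero(ensemble.spikes[:, :, cols])
    return pd.DataFrame({"trial": trial, "neuron": neuron, "time": time + lo})


def events_to_ensemble(frame: pd.DataFrame, params: NetworkParameters,
                       t_steps: int, n_trials: int) -> TrialEnsemble:
    """Rebuild a (burn-in-free) ensemble from sparse events."""
    spikes = np.zeros((n_trials, params.n_neurons, t_steps), dtype=np.uint8)
    spikes[frame["trial"], frame["neuron"], frame["time"]] = 1
    return TrialEnsemble(spikes=spikes, params=params, stimulus=None,
                         burn_in=0, t_steps=t_steps)


def save_ensemble_npz(path, ensemble: TrialEnsemble) -> None:
    """Dense binary container (compressed npz) for speed."""
    np.savez_compressed(
        path, spikes=ensemble.spikes, burn_in=ensemble.burn_in,
        t_steps=ensemble.t_steps,
        master_seed=-1 if ensemble.master_seed is None else ensemble.master_seed,
        params=json.dumps(params_to_dict(ensemble.params)),
    )


def load_ensemble_npz(path) -> TrialEnsemble:
    with np.load(path, allow_pickle=False) as data:
        params = params_from_dict(json.loads(str(data["params"])))
        seed = int(data["master_seed"])
        return TrialEnsemble(
            spikes=data["spikes"], params=params, stimulus=None,
            burn_in=int(data["burn_in"]), t_steps=int(data["t_steps"]),
            master_seed=None if seed < 0 else seed,
        )


# ---------------------------------------------------------------------------
# Traces, kernels, stimulus matrices
# ---------------------------------------------------------------------------

def trace_to_frame(trace: ResponseTrace) -> pd.DataFrame:
    """Tidy rows (n, value, stderr, method, observable)."""
    return pd.DataFrame({
        "n": trace.times,
        "value": trace.values,
        "stderr": np.nan if trace.stderr is None else trace.stderr,
        "method": trace.method,
        "observable": trace.observable,
    })


def save_traces_csv(path, traces) -> None:
    pd.concat([trace_to_frame(t) for t in traces], ignore_index=True).to_csv(
        path, index=False)


def kernel_to_frame(kernel) -> pd.DataFrame:
    """Tidy kernel rows (neuron, m, value, nu, horizon, method)."""
    n, width = kernel.kernel.shape
    rows = []
    for k in range(n):
        for m in range(1, width + 1):
            rows.append({
                "neuron": k, "m": m, "value": kernel.kernel[k, m - 1],
                "nu": kernel.nu[k], "horizon": int(kernel.horizons[k]),
                "gamma": kernel.gamma, "scale": kernel.scale,
                "method": kernel.method,
            })
    return pd.DataFrame(rows)


def save_stimulus_csv(path, stimulus: StimulusField) -> None:
    """Neurons x steps matrix with the onset stored in the header comment."""
    frame = pd.DataFrame(stimulus.values)
    with open(path, "w") as fh:
        fh.write(f"# t0={stimulus.t0}\n")
        frame.to_csv(fh, index=False)


def load_stimulus_csv(path) -> StimulusField:
    with open(path) as fh:
        header = fh.readline()
        t0 = int(header.strip().split("t0=")[1]) if "t0=" in header else 0
        frame = pd.read_csv(fh)
    return StimulusField(frame.to_numpy(dtype=float), t0=t0)
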