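"""Reproducibility plumbing: run configs, fixture specs, CSV serialization.

Every stochastic artifact carries an explicit seed and a configuration hash
so a run can be replayed bit-identically; tabular results go to plain CSV
with a JSON sidecar describing columns and provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .stimulus import PeriodicStimulus, fourier_spectrum, harmonic_mix, shape_library

__all__ = [
    "RunConfig",
    "FixtureSpec",
    "config_hash",
    "generate_stimulus_fixture",
    "write_table",
    "read_table",
    "run_report",
    "alpha_curve_to_frame",
    "phase_model_to_frame",
]


def config_hash(params: dict) -> str:
    """Stable short hash over all numeric/str parameters of a run."""
    canon = json.dumps(params, sort_keys=True, default=_canon)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _canon(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


@dataclass
class RunConfig:
    """Selector + parameter block + seed for one reproducible run."""

    module: str
    operation: str
    params: dict
    seed: int
    outdir: str = "results"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("every run carries an explicit seed")

    @property
    def hash(self) -> str:
        return config_hash(dict(module=self.module, operation=self.operation,
                                seed=self.seed, **self.params))

    def stamp(self) -> dict:
        return dict(module=self.module, operation=self.operation,
                    seed=self.seed, config_hash=self.hash,
                    code_version=__version__)


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture; regeneration from the
    spec is bit-identical (all randomness flows through the seed)."""

    family: str                  # polynomial-model | prc-table | stimulus | tissue
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def hash(self) -> str:
        return config_hash(dict(family=self.family, seed=self.seed, **self.params))


def generate_stimulus_fixture(spec: FixtureSpec) -> PeriodicStimulus:
    """Stimulus fixtures: named shapes, harmonic mixes, and band-limited
    random waveforms with prescribed spectra (zero-mean by construction)."""
    if spec.family != "stimulus":
        raise ValueError("not a stimulus fixture spec")
    p = dict(spec.params)
    T = float(p.get("T", 10.0))
    K = int(p.get("K", 16))
    kind = p.get("kind", "sine")
    if kind in shape_library(T):
        return fourier_spectrum(shape_library(T)[kind], T, K, label=kind)
    if kind == "random-band-limited":
        rng = np.random.default_rng(spec.seed)
        bw = int(p.get("bandwidth", 4))
        a = rng.standard_normal(bw) * np.asarray(p.get("decay", 1.0)) ** np.arange(bw)
        b = rng.standard_normal(bw)
        return fourier_spectrum(harmonic_mix(T, a, b), T, max(K, bw),
                                label=f"rand{spec.seed}")
    if kind == "harmonics":
        return fourier_spectrum(harmonic_mix(T, p["a"], p["b"]), T, K,
                                label="harmonics")
    raise ValueError(f"unknown stimulus kind {kind!r}")


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """CSV plus JSON sidecar (units/provenance); ``meta`` must include a
    config hash for stochastic results."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    side = dict(columns=list(df.columns), code_version=__version__)
    if meta:
        side.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=2, default=_canon))


def read_table(path):
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, meta


def alpha_curve_to_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(dict(
        T_ms=curve.T_grid,
        re_alpha=curve.alpha.real,
        im_alpha=curve.alpha.imag,
        flagged=curve.resonance_mask.astype(int),
    ))


def phase_model_to_frame(phase) -> pd.DataFrame:
    return pd.DataFrame(dict(theta=phase.theta_grid, Z=phase.Z, V=phase.V))


def run_report(results_dir) -> dict:
    """Summarize the serialized results in a directory.

    Every table must carry a config hash in its sidecar (stochastic records
    additionally a seed); missing provenance is a hard failure.  Returns a
    manifest mapping file names to their provenance; reruns on identical
    inputs give identical manifests.
    """
    results_dir = Path(results_dir)
    files = sorted(results_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no result tables in {results_dir}")
    manifest = {}
    for f in files:
        df, meta = read_table(f)
        if "config_hash" not in meta:
            raise ValueError(f"{f.name}: missing config hash in sidecar")
        if meta.get("stochastic") and "seed" not in meta:
            raise ValueError(f"{f.name}: stochastic record without a seed")
        csum = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
        manifest[f.name] = dict(rows=len(df), checksum=csum,
                                config_hash=meta["config_hash"])
    return manifest
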