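"""Geoaccumulation index, Hakanson potential ecological risk, and classes.

I_geo = log2(Cn / (1.5 Bn)) with the Muller 1.5 background-correction factor;
Er = Tr * Cn / Bn; RI = sum of Er over the eight metals. Class boundaries are
half-open [lower, upper) and configurable; defaults follow the Muller and
Hakanson scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (METALS, BackgroundValues, SampleTable, SchemaError,
                      _load_yaml)

#: Sentinel class for a zero concentration (I_geo would be -inf).
BELOW_SCALE = "below_scale"


@dataclass(frozen=True)
class ToxicityCoefficients:
    """Hakanson toxic-response factors plus index class scales."""

    tr: dict[str, float]
    classes: dict[str, dict]

    def __post_init__(self):
        for m in METALS:
            if m not in self.tr:
                raise SchemaError(f"toxicity registry missing metal {m!r}")
            if not self.tr[m] > 0:
                raise SchemaError(f"Tr for {m!r} must be > 0")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ToxicityCoefficients":
        raw = _load_yaml(path, "toxicity.yaml")
        return cls(tr={m: float(v) for m, v in raw["tr"].items()},
                   classes=raw["classes"])


def igeo(conc: float | np.ndarray, background: float) -> float | np.ndarray:
    """Geoaccumulation index; conc = 0 yields -inf (classified BELOW_SCALE)."""
    if background <= 0:
        raise ValueError("background must be > 0")
    conc = np.asarray(conc, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.log2(conc / (1.5 * background))
    return float(out) if out.ndim == 0 else out


def er(conc: float | np.ndarray, background: float, tr: float) -> float | np.ndarray:
    """Single-metal potential ecological risk Tr * Cn / Bn."""
    if background <= 0:
        raise ValueError("background must be > 0")
    if tr <= 0:
        raise ValueError("toxic-response factor must be > 0")
    conc = np.asarray(conc, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentration must be >= 0")
    out = tr * conc / background
    return float(out) if out.ndim == 0 else out


def ri(er_values: dict[str, float]) -> float:
    """Cumulative ecological risk: sum of Er over all eight metals."""
    missing = [m for m in METALS if m not in er_values]
    if missing:
        raise ValueError(f"partial RI forbidden; missing Er for {missing}")
    return float(sum(er_values[m] for m in METALS))


def exceedance_ratio(conc_mean: float, background: float) -> float:
    """Fold ratio Cn / Bn of a mean concentration over its background."""
    if background <= 0:
        raise ValueError("background must be > 0")
    return float(conc_mean) / float(background)


def classify(index: str, value: float,
             tox: ToxicityCoefficients | None = None) -> str:
    """Ordinal class label for an igeo/er/ri value (half-open bands)."""
    tox = tox or ToxicityCoefficients.load()
    if index not in tox.classes:
        raise ValueError(f"unknown index {index!r}")
    if value == -math.inf:
        return BELOW_SCALE
    if not math.isfinite(value):
        raise ValueError(f"non-finite {index} value")
    scale = tox.classes[index]
    bounds, labels = scale["bounds"], scale["labels"]
    for b, lab in zip(bounds, labels):
        if value < b:
            return lab
    return labels[-1]


def compute_indices(samples: SampleTable,
                    background: BackgroundValues,
                    tox: ToxicityCoefficients | None = None) -> pd.DataFrame:
    """Per-sample I_geo, contamination factor, Er, RI and class labels.

    Indices are computed per sample against the layer-specific background;
    layer aggregation (arithmetic means) is left to the caller, matching how
    survey tables report them.
    """
    tox = tox or ToxicityCoefficients.load()
    rows = []
    for _, r in samples.df.iterrows():
        rec = {"site_id": r["site_id"], "layer": r["layer"]}
        er_vals = {}
        for m in METALS:
            b = background.value(m, r["layer"])
            c = float(r[m])
            rec[f"cf_{m}"] = c / b
            rec[f"igeo_{m}"] = igeo(c, b)
            rec[f"igeo_class_{m}"] = classify("igeo", rec[f"igeo_{m}"], tox)
            e = er(c, b, tox.tr[m])
            er_vals[m] = e
            rec[f"er_{m}"] = e
            rec[f"er_class_{m}"] = classify("er", e, tox)
        rec["ri"] = ri(er_vals)
        rec["ri_class"] = classify("ri", rec["ri"], tox)
        rows.append(rec)
    return pd.DataFrame(rows)
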