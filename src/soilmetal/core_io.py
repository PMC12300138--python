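"""Data model, parameter registries and descriptive statistics.

Concentrations are carried in a pandas DataFrame with one row per physical
sample (site x layer) and one column per metal, in mg/kg. Detection limits
declared in ug/g are numerically equal to mg/kg and are stored as mg/kg.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

METALS = ("Cu", "Zn", "Ni", "Pb", "Cr", "Cd", "As", "Hg")
LAYERS = ("surface", "deep")
CROP_TYPES = ("leafy", "fruit", "root", "inflorescence", "sugarcane", "banana", "none")

META_COLUMNS = ("site_id", "layer", "crop_type")


class SchemaError(ValueError):
    """A required column or registry entry is missing or malformed."""


class IntegrityError(ValueError):
    """Row-level data violates the table contract (negatives, duplicates)."""


def _read_registry(name: str) -> dict:
    ref = importlib.resources.files("soilmetal.data").joinpath(name)
    return yaml.safe_load(ref.read_text())


def _load_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is None:
        return _read_registry(default_name)
    return yaml.safe_load(Path(path).read_text())


@dataclass(frozen=True)
class BackgroundValues:
    """Layer-specific geochemical background concentrations (mg/kg)."""

    bgv: dict[str, dict[str, float]]

    def __post_init__(self):
        for m in METALS:
            if m not in self.bgv:
                raise SchemaError(f"background registry missing metal {m!r}")
            for layer in LAYERS:
                if layer not in self.bgv[m]:
                    raise SchemaError(
                        f"background for {m!r} must give both layers; missing {layer!r}"
                    )
                if not self.bgv[m][layer] > 0:
                    raise SchemaError(f"background for {m!r}/{layer!r} must be > 0")

    def value(self, metal: str, layer: str) -> float:
        return float(self.bgv[metal][layer])

    def vector(self, layer: str) -> np.ndarray:
        return np.array([self.bgv[m][layer] for m in METALS], dtype=float)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "BackgroundValues":
        raw = _load_yaml(path, "background.yaml")
        return cls(bgv={m: dict(v) for m, v in raw["bgv"].items()})


@dataclass(frozen=True)
class DetectionLimits:
    """Method detection limits per metal, stored in mg/kg (= ug/g)."""

    mdl: dict[str, float]

    def __post_init__(self):
        for m in METALS:
            if m not in self.mdl:
                raise SchemaError(f"detection-limit registry missing metal {m!r}")
            if not self.mdl[m] > 0:
                raise SchemaError(f"detection limit for {m!r} must be > 0")

    def vector(self) -> np.ndarray:
        return np.array([self.mdl[m] for m in METALS], dtype=float)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "DetectionLimits":
        raw = _load_yaml(path, "detection_limits.yaml")
        return cls(mdl={m: float(v) for m, v in raw["mdl"].items()})


@dataclass
class SampleTable:
    """Validated per-sample metal concentrations with site/layer/crop metadata.

    ``df`` holds columns site_id, layer, crop_type and the eight metals.
    ``censored`` marks values at or below the detection limit (recorded at
    load time when limits are supplied; never transformed).
    """

    df: pd.DataFrame
    censored: pd.DataFrame | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.df = validate_samples(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.df["site_id"]))

    def layer(self, layer: str) -> pd.DataFrame:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return self.df[self.df["layer"] == layer].reset_index(drop=True)

    def matrix(self, layer: str) -> np.ndarray:
        """(n_samples, 8) concentration matrix for one layer, metal order METALS."""
        return self.layer(layer)[list(METALS)].to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> None:
        cols = list(META_COLUMNS) + list(METALS)
        self.df[cols].to_csv(path, index=False, float_format="%.10g")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in list(META_COLUMNS) + list(METALS) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["site_id"] = df["site_id"].astype(str)
    df["crop_type"] = df["crop_type"].fillna("none").replace("", "none")
    bad_layer = set(df["layer"]) - set(LAYERS)
    if bad_layer:
        raise SchemaError(f"unknown layer value(s): {sorted(bad_layer)}")
    bad_crop = set(df["crop_type"]) - set(CROP_TYPES)
    if bad_crop:
        raise SchemaError(f"unknown crop_type value(s): {sorted(bad_crop)}")

    conc = df[list(METALS)].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(conc.to_numpy()) | (conc.to_numpy() < 0)
    if bad.any():
        rows = df.index[bad.any(axis=1)].tolist()
        detail = []
        for r in rows[:10]:
            cols = [m for i, m in enumerate(METALS) if bad[df.index.get_loc(r), i]]
            detail.append(f"row {r} ({df.loc[r, 'site_id']}/{df.loc[r, 'layer']}): {cols}")
        raise IntegrityError(
            "negative or non-numeric concentration(s): " + "; ".join(detail)
        )
    df[list(METALS)] = conc

    dup = df.duplicated(subset=["site_id", "layer"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["site_id", "layer"]].drop_duplicates().to_records(index=False)
        raise IntegrityError(f"duplicate (site_id, layer) pairs: {list(pairs)}")
    return df.reset_index(drop=True)


def load_samples(
    path: str | Path,
    mdl: DetectionLimits | None = None,
    schema: dict[str, str] | None = None,
) -> SampleTable:
    """Read a concentration CSV into a validated :class:`SampleTable`.

    ``schema`` optionally maps canonical column names to the names used in the
    file. When detection limits are given, values at or below the limit are
    flagged in ``table.censored`` but left untouched.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    table = SampleTable(df)
    if mdl is not None:
        lim = mdl.vector()
        cens = table.df[list(METALS)].to_numpy(dtype=float) <= lim[None, :]
        table.censored = pd.DataFrame(cens, columns=list(METALS))
        n = int(cens.sum())
        if n:
            table.diagnostics.append(f"{n} value(s) at or below the detection limit")
    return table


def summarize(samples: SampleTable) -> pd.DataFrame:
    """Per metal x layer min/max/mean/CV (sample sd over mean).

    Returns a DataFrame indexed by (metal, layer). A zero mean leaves CV as
    NaN and is reported in ``samples.diagnostics`` rather than dropped.
    """
    rows = []
    for layer in LAYERS:
        sub = samples.layer(layer)
        if len(sub) < 2:
            raise ValueError(f"need at least 2 samples in layer {layer!r}")
        for m in METALS:
            x = sub[m].to_numpy(dtype=float)
            mean = x.mean()
            sd = x.std(ddof=1)
            if mean == 0.0:
                cv = np.nan
                samples.diagnostics.append(f"CV undefined for {m}/{layer}: zero mean")
            else:
                cv = sd / mean
            rows.append(
                {"metal": m, "layer": layer, "min": x.min(), "max": x.max(),
                 "mean": mean, "cv": cv}
            )
    return pd.DataFrame(rows).set_index(["metal", "layer"])


def pair_layers(samples: SampleTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Aligned (surface, deep) concentration matrices over sites with both layers.

    Sites missing either layer are dropped with a note in ``diagnostics``;
    if no complete pair remains a ValueError is raised.
    """
    surf = samples.layer("surface").set_index("site_id")
    deep = samples.layer("deep").set_index("site_id")
    common = [s for s in samples.sites if s in surf.index and s in deep.index]
    dropped = [s for s in samples.sites if s not in common]
    if dropped:
        samples.diagnostics.append(
            f"dropped {len(dropped)} unpaired site(s): {dropped[:5]}"
        )
    if not common:
        raise ValueError("no site has both surface and deep samples")
    s_mat = surf.loc[common, list(METALS)].to_numpy(dtype=float)
    d_mat = deep.loc[common, list(METALS)].to_numpy(dtype=float)
    return s_mat, d_mat, common


def load_reference_summary() -> dict:
    """Published survey summary (Table-scale means/CV and PMF profiles)."""
    return _read_registry("reference_summary.yaml")
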