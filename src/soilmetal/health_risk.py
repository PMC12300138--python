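"""Deterministic and Monte Carlo human health risk from soil heavy metals.

Average daily doses follow the USEPA residential dose model over four
pathways — incidental soil ingestion, dermal contact, dust inhalation, and
food ingestion via crop bioconcentration factors:

    ingest: ADD = C * IngR * EF * ED * CF / (BW * AT)
    dermal: ADD = C * SA * AF * ABS * EF * ED * CF / (BW * AT)
    inhale: ADD = C * InhR * EF * ED / (PEF * BW * AT)
    food:   ADD = C * BCF * IR_food * EF * ED / (BW * AT)

Non-carcinogenic endpoints use AT_nc (= ED * 365 by default), carcinogenic
endpoints use lifetime AT_ca. HQ = ADD/RfD summed to HI; CR = ADD * SF summed
to TCR. The Monte Carlo layer replaces selected exposure factors by normal
(zero-truncated) or triangular distributions and draws the concentration term
from the empirical per-layer sample distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import METALS, SampleTable, SchemaError, _load_yaml

PATHWAYS = ("ingest", "dermal", "inhale", "food")
POPULATIONS = ("child", "adult")

_PARAM_NAMES = ("IngR", "InhR", "SA", "AF", "ABS", "EF", "ED", "BW",
                "AT_nc", "AT_ca", "PEF", "CF", "IR_food")


@dataclass(frozen=True)
class DistributionSpec:
    """Point value, normal(mean, sd) truncated at zero, or triangular."""

    kind: str
    params: tuple

    @classmethod
    def parse(cls, spec) -> "DistributionSpec":
        if isinstance(spec, (int, float)):
            return cls("point", (float(spec),))
        if not isinstance(spec, dict) or len(spec) != 1:
            raise SchemaError(f"malformed distribution spec: {spec!r}")
        (kind, body), = spec.items()
        if kind == "value":
            return cls("point", (float(body),))
        if kind == "normal":
            mean, sd = float(body["mean"]), float(body["sd"])
            if sd <= 0:
                raise SchemaError("normal sd must be > 0")
            return cls("normal", (mean, sd))
        if kind == "triangular":
            lo, mode, hi = (float(body[k]) for k in ("min", "mode", "max"))
            if not lo <= mode <= hi or lo == hi:
                raise SchemaError("triangular needs min <= mode <= max, min < max")
            return cls("triangular", (lo, mode, hi))
        raise SchemaError(f"unknown distribution kind {kind!r}")

    @property
    def central(self) -> float:
        """Value used by the deterministic pipeline (point/mean/mode)."""
        return self.params[0] if self.kind != "triangular" else self.params[1]

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.params[0])
        if self.kind == "triangular":
            return rng.triangular(*self.params, size)
        mean, sd = self.params
        out = rng.normal(mean, sd, size)
        bad = out <= 0
        while bad.any():  # physical parameters cannot be negative
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = out <= 0
        return out


@dataclass(frozen=True)
class ExposureParameters:
    """Per-population exposure factors as distribution specs."""

    populations: dict[str, dict[str, DistributionSpec]]

    def __post_init__(self):
        for pop, params in self.populations.items():
            missing = [p for p in _PARAM_NAMES if p not in params]
            if missing:
                raise SchemaError(f"population {pop!r} missing {missing}")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ExposureParameters":
        raw = _load_yaml(path, "exposure.yaml")
        pops = {pop: {name: DistributionSpec.parse(spec)
                      for name, spec in params.items()}
                for pop, params in raw["populations"].items()}
        return cls(populations=pops)

    def central(self, population: str) -> dict[str, float]:
        return {k: v.central for k, v in self.populations[population].items()}


@dataclass(frozen=True)
class ToxicologicalReference:
    """RfD and SF per metal per pathway; None disables the term."""

    rfd: dict[str, dict[str, float | None]]
    sf: dict[str, dict[str, float | None]]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ToxicologicalReference":
        raw = _load_yaml(path, "toxref.yaml")
        for table in (raw["rfd"], raw["sf"]):
            for m, entry in table.items():
                for pw, v in entry.items():
                    if v is not None and not v > 0:
                        raise SchemaError(f"nonpositive entry for {m}/{pw}")
        return cls(rfd=raw["rfd"], sf=raw["sf"])


@dataclass(frozen=True)
class BioconcentrationFactors:
    """Crop fresh-weight / soil concentration ratios per crop and metal."""

    bcf: dict[str, dict[str, float]]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "BioconcentrationFactors":
        raw = _load_yaml(path, "bcf.yaml")
        return cls(bcf=raw["bcf"])

    def vector(self, crop: str) -> np.ndarray:
        """(8,) BCF vector; the 'none' crop zeroes the food pathway."""
        if crop == "none":
            return np.zeros(len(METALS))
        if crop not in self.bcf:
            raise SchemaError(f"no BCF entry for crop {crop!r}")
        return np.array([self.bcf[crop][m] for m in METALS], dtype=float)


def add_pathway(conc, pathway: str, params: dict[str, float],
                bcf=None, endpoint: str = "nc"):
    """Average daily dose (mg/kg/day) for one pathway.

    ``conc`` in mg/kg; ``params`` is a realization of the exposure factors;
    ``bcf`` (required iff pathway == "food") is the crop bioconcentration
    factor. ``endpoint`` selects AT_nc or AT_ca.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    at = params["AT_nc"] if endpoint == "nc" else params["AT_ca"]
    base = params["EF"] * params["ED"] / (params["BW"] * at)
    if pathway == "ingest":
        return conc * params["IngR"] * params["CF"] * base
    if pathway == "dermal":
        return conc * params["SA"] * params["AF"] * params["ABS"] * params["CF"] * base
    if pathway == "inhale":
        return conc * params["InhR"] / params["PEF"] * base
    if bcf is None:
        raise ValueError("food pathway requires a bioconcentration factor")
    return conc * bcf * params["IR_food"] * base


def hq(add, rfd: float):
    """Hazard quotient ADD / RfD."""
    if not rfd > 0:
        raise ValueError("RfD must be > 0")
    return add / rfd


def hi(hqs) -> float:
    """Hazard index: sum of hazard quotients."""
    return float(np.sum(list(hqs)))


def cr(add, sf: float):
    """Cancer risk ADD * SF."""
    if not sf > 0:
        raise ValueError("slope factor must be > 0")
    return add * sf


def tcr(crs) -> float:
    """Total cancer risk: sum of pathway/metal cancer risks."""
    return float(np.sum(list(crs)))


@dataclass
class RiskResult:
    """Risk quantities for one population x layer.

    ``hq_table``/``cr_table`` hold mean HQ / CR per (metal, pathway);
    ``hi_samples``/``tcr_samples`` are per-iteration totals (length 1 for
    deterministic runs). Summaries report mean and 5/50/95 percentiles.
    """

    population: str
    layer: str
    n_iter: int
    seed: int | None
    hq_table: pd.DataFrame
    cr_table: pd.DataFrame
    hi_samples: np.ndarray
    tcr_samples: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def hi(self) -> float:
        return float(self.hi_samples.mean())

    @property
    def tcr(self) -> float:
        return float(self.tcr_samples.mean())

    def summary(self, endpoint: str) -> dict[str, float]:
        x = self.hi_samples if endpoint == "HI" else self.tcr_samples
        return {"mean": float(x.mean()),
                "p05": float(np.percentile(x, 5)),
                "p50": float(np.percentile(x, 50)),
                "p95": float(np.percentile(x, 95))}

    def cumulative_curve(self, endpoint: str, n_points: int = 101) -> pd.DataFrame:
        """Cumulative probability curve: P(X <= x) on an endpoint's samples."""
        x = np.sort(self.hi_samples if endpoint == "HI" else self.tcr_samples)
        q = np.linspace(0.0, 1.0, n_points)
        vals = np.quantile(x, q)
        return pd.DataFrame({"value": vals, "cum_prob": q})


def _food_conc_terms(samples: SampleTable, layer: str,
                     bcfs: BioconcentrationFactors) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample soil concentrations and crop-adjusted food terms, (n, 8)."""
    sub = samples.layer(layer)
    conc = sub[list(METALS)].to_numpy(dtype=float)
    bmat = np.vstack([bcfs.vector(c) for c in sub["crop_type"]])
    return conc, conc * bmat


def _risk_tables(conc_nc, conc_ca, food_nc, food_ca, params, refs):
    """Mean HQ and CR per (metal, pathway) from per-iteration arrays."""
    hq_rows, cr_rows = {}, {}
    hi_tot = 0.0
    tcr_tot = 0.0
    for j, m in enumerate(METALS):
        for pw in PATHWAYS:
            c_nc = food_nc[..., j] if pw == "food" else conc_nc[..., j]
            c_ca = food_ca[..., j] if pw == "food" else conc_ca[..., j]
            bcf = 1.0 if pw == "food" else None  # folded into the food term
            rfd = refs.rfd.get(m, {}).get(pw)
            sf = refs.sf.get(m, {}).get(pw)
            if rfd is not None:
                q = hq(add_pathway(c_nc, pw, params, bcf=bcf, endpoint="nc"), rfd)
                hq_rows[(m, pw)] = q
                hi_tot = hi_tot + q
            if sf is not None:
                r = cr(add_pathway(c_ca, pw, params, bcf=bcf, endpoint="ca"), sf)
                cr_rows[(m, pw)] = r
                tcr_tot = tcr_tot + r
    return hq_rows, cr_rows, hi_tot, tcr_tot


def _tables_from_rows(rows: dict) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["metal", "pathway"])
    return pd.DataFrame({"mean": [float(np.mean(v)) for v in rows.values()]},
                        index=idx)


def deterministic_risk(samples: SampleTable, layer: str,
                       params: ExposureParameters,
                       refs: ToxicologicalReference,
                       bcfs: BioconcentrationFactors,
                       population: str) -> RiskResult:
    """Point-estimate risk at central exposure factors and layer-mean
    concentrations (food term averaged over per-site crop assignment)."""
    conc, food = _food_conc_terms(samples, layer, bcfs)
    c_mean, f_mean = conc.mean(axis=0), food.mean(axis=0)
    p = params.central(population)
    hq_rows, cr_rows, hi_tot, tcr_tot = _risk_tables(c_mean, c_mean,
                                                     f_mean, f_mean, p, refs)
    res = RiskResult(population=population, layer=layer, n_iter=1, seed=None,
                     hq_table=_tables_from_rows(hq_rows),
                     cr_table=_tables_from_rows(cr_rows),
                     hi_samples=np.atleast_1d(np.asarray(hi_tot, dtype=float)),
                     tcr_samples=np.atleast_1d(np.asarray(tcr_tot, dtype=float)))
    if (food == 0).all():
        res.flags.append("food pathway inactive: no cropped samples")
    return res


def monte_carlo_risk(samples: SampleTable, params: ExposureParameters,
                     refs: ToxicologicalReference,
                     bcfs: BioconcentrationFactors,
                     n_iter: int = 10000, seed: int = 0,
                     populations=POPULATIONS, layers=("surface", "deep"),
                     concentration: str = "resample") -> dict[tuple[str, str], RiskResult]:
    """Monte Carlo risk per (population, layer).

    Stochastic exposure factors are drawn from their distribution specs; the
    concentration term is either a per-iteration resample of a whole sample
    row (keeping metal correlations and the site's crop) or the layer mean.
    One master seed spawns one substream per population x layer.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if concentration not in ("resample", "mean"):
        raise ValueError("concentration must be 'resample' or 'mean'")
    streams = np.random.SeedSequence(seed).spawn(len(populations) * len(layers))
    results: dict[tuple[str, str], RiskResult] = {}
    k = 0
    for pop in populations:
        for layer in layers:
            rng = np.random.default_rng(streams[k]); k += 1
            conc, food = _food_conc_terms(samples, layer, bcfs)
            if concentration == "resample":
                idx = rng.integers(0, conc.shape[0], n_iter)
                c, f = conc[idx], food[idx]
            else:
                c = np.broadcast_to(conc.mean(axis=0), (n_iter, len(METALS)))
                f = np.broadcast_to(food.mean(axis=0), (n_iter, len(METALS)))
            draws = {name: spec.draw(rng, n_iter)
                     for name, spec in params.populations[pop].items()}
            hq_rows, cr_rows, hi_tot, tcr_tot = _risk_tables(c, c, f, f,
                                                             draws, refs)
            res = RiskResult(population=pop, layer=layer, n_iter=n_iter,
                             seed=seed,
                             hq_table=_tables_from_rows(hq_rows),
                             cr_table=_tables_from_rows(cr_rows),
                             hi_samples=np.asarray(hi_tot, dtype=float),
                             tcr_samples=np.asarray(tcr_tot, dtype=float))
            if (food == 0).all():
                res.flags.append("food pathway inactive: no cropped samples")
            results[(pop, layer)] = res
    return results


def risk_contributions(result: RiskResult, by: str = "metal") -> pd.DataFrame:
    """Fractions of HI and TCR attributable to each metal or pathway."""
    if by not in ("metal", "pathway"):
        raise ValueError("by must be 'metal' or 'pathway'")
    out = {}
    for endpoint, table in (("HI", result.hq_table), ("TCR", result.cr_table)):
        g = table["mean"].groupby(level=by).sum()
        total = g.sum()
        if total <= 0:
            result.flags.append(f"{endpoint} total is zero; contributions undefined")
            out[endpoint] = g * np.nan
        else:
            out[endpoint] = g / total
    return pd.DataFrame(out)
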