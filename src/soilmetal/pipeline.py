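"""End-to-end orchestration: simulate -> indices -> risk -> sources -> report.

Every run is a pure function of (input data, registries, seeds). The report
bundle is a machine-readable JSON plus a Markdown digest; all numbers in the
report are taken from the stage outputs written next to it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (LAYERS, METALS, BackgroundValues, DetectionLimits,
                      SampleTable, load_samples, pair_layers, summarize)
from .health_risk import (BioconcentrationFactors, ExposureParameters,
                          ToxicologicalReference, monte_carlo_risk,
                          risk_contributions)
from .pollution_indices import ToxicityCoefficients, compute_indices
from .source_apportionment import (assign_factor_labels, build_uncertainty,
                                   compare_layers, contribution_percent,
                                   floor_at_mdl, pca_varimax, pmf_fit)
from .synthetic_data import SyntheticConfig, generate, truth_contributions

HI_THRESHOLD = 1.0
TCR_THRESHOLD = 1.0e-4


@dataclass
class RunConfig:
    out_dir: str = "soilmetal_run"
    input_csv: str | None = None          # None -> simulate
    n_sites: int = 72
    seed: int = 1
    n_iter: int = 10000
    pmf_restarts: int = 20
    pmf_delta: float = 0.1
    stages: tuple = ("simulate", "indices", "risk", "sources")
    background: str | None = None         # registry overrides (paths)
    detection_limits: str | None = None
    toxicity: str | None = None
    exposure: str | None = None
    toxref: str | None = None
    bcf: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for attr in ("input_csv", "background", "detection_limits", "toxicity",
                     "exposure", "toxref", "bcf"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns the report dict. Any stage failure propagates with its own
    diagnostics; outputs written before the failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    report: dict = {"tool_version": __version__, "config": asdict(config),
                    "config_hash": cfg_hash, "seeds": {"master": config.seed},
                    "stages": {}}

    background = BackgroundValues.load(config.background)
    mdl = DetectionLimits.load(config.detection_limits)
    tox = ToxicityCoefficients.load(config.toxicity)

    # ---- data ------------------------------------------------------------
    if config.input_csv is not None:
        samples = load_samples(config.input_csv, mdl=mdl)
        report["stages"]["input"] = {"path": str(config.input_csv),
                                     "n_samples": len(samples)}
    else:
        syn = SyntheticConfig(n_sites=config.n_sites, seed=config.seed)
        samples, truth = generate(syn)
        samples.write_csv(out / "data.csv")
        truth_payload = {
            "profiles": truth.profiles,
            "site_order": truth.site_order,
            "scores": {lay: truth.scores[lay] for lay in LAYERS},
            "fractions": {lay: truth_contributions(truth, lay).to_dict()
                          for lay in LAYERS},
        }
        _write_json(out / "truth.json", truth_payload)
        report["stages"]["simulate"] = {"n_sites": config.n_sites,
                                        "seed": config.seed,
                                        "out": "data.csv"}

    desc = summarize(samples)
    desc.to_csv(out / "summary.csv")
    report["stages"]["descriptives"] = {
        "out": "summary.csv",
        "mean": {f"{m}_{lay}": float(desc.loc[(m, lay), "mean"])
                 for m in METALS for lay in LAYERS},
    }

    # ---- indices ---------------------------------------------------------
    if "indices" in config.stages:
        idx = compute_indices(samples, background, tox)
        idx.to_csv(out / "indices.csv", index=False)
        by_layer = {}
        for lay in LAYERS:
            sub = idx[idx["layer"] == lay]
            by_layer[lay] = {
                "mean_ri": float(sub["ri"].mean()),
                "ri_class_counts": sub["ri_class"].value_counts().to_dict(),
                "mean_igeo": {m: float(sub[f"igeo_{m}"].mean()) for m in METALS},
                "mean_er": {m: float(sub[f"er_{m}"].mean()) for m in METALS},
            }
        report["stages"]["indices"] = {"out": "indices.csv", **by_layer}

    # ---- health risk -----------------------------------------------------
    if "risk" in config.stages:
        params = ExposureParameters.load(config.exposure)
        refs = ToxicologicalReference.load(config.toxref)
        bcfs = BioconcentrationFactors.load(config.bcf)
        mc = monte_carlo_risk(samples, params, refs, bcfs,
                              n_iter=config.n_iter, seed=config.seed)
        risk_payload, risk_summary = {}, {}
        for (pop, lay), res in mc.items():
            s_hi, s_tcr = res.summary("HI"), res.summary("TCR")
            risk_payload.setdefault(pop, {})[lay] = {
                "HI": {**s_hi,
                       "curve": res.cumulative_curve("HI").to_dict("list")},
                "TCR": {**s_tcr,
                        "curve": res.cumulative_curve("TCR").to_dict("list")},
                "contrib_metal": risk_contributions(res, "metal").to_dict(),
                "contrib_pathway": risk_contributions(res, "pathway").to_dict(),
                "flags": res.flags,
            }
            risk_summary[f"{pop}_{lay}"] = {
                "HI_mean": s_hi["mean"], "TCR_mean": s_tcr["mean"],
                "HI_exceeds": s_hi["mean"] > HI_THRESHOLD,
                "TCR_exceeds": s_tcr["mean"] > TCR_THRESHOLD,
                "HI_p95_exceeds": s_hi["p95"] > HI_THRESHOLD,
                "TCR_p95_exceeds": s_tcr["p95"] > TCR_THRESHOLD,
            }
        _write_json(out / "risk.json", risk_payload)
        report["stages"]["risk"] = {"out": "risk.json",
                                    "n_iter": config.n_iter,
                                    "thresholds": {"HI": HI_THRESHOLD,
                                                   "TCR": TCR_THRESHOLD},
                                    "summary": risk_summary}

    # ---- sources ---------------------------------------------------------
    if "sources" in config.stages:
        s_mat, d_mat, _sites = pair_layers(samples)
        contribs = {}
        for lay, mat in (("surface", s_mat), ("deep", d_mat)):
            pca = pca_varimax(mat)
            x = floor_at_mdl(mat, mdl)
            u = build_uncertainty(x, mdl, config.pmf_delta)
            model = pmf_fit(x, u, k=2, n_restarts=config.pmf_restarts,
                            seed=config.seed)
            labelled = assign_factor_labels(model, background)
            contribs[lay] = labelled
            _write_json(out / f"sources_{lay}.json", {
                "Q": model.Q,
                "Q_per_restart": [r["Q"] for r in model.restarts],
                "converged": model.converged,
                "G": model.G, "F": model.F,
                "profile_percent": contribution_percent(model.F).to_dict(),
                "labelled_percent": labelled.percent.to_dict(),
                "label_scores": labelled.label_scores,
                "pca": {"kmo": pca.kmo, "bartlett_p": pca.bartlett_p,
                        "n_retained": pca.n_retained,
                        "eigenvalues": pca.eigenvalues,
                        "explained_variance": pca.explained_variance,
                        "loadings": pca.loadings.to_dict()},
                "flags": labelled.flags,
            })
            report["stages"].setdefault("sources", {})[lay] = {
                "out": f"sources_{lay}.json", "Q": model.Q,
                "kmo": pca.kmo, "pca_retained": pca.n_retained,
                "anthropogenic_percent":
                    labelled.anthropogenic.round(1).to_dict(),
            }
        delta = compare_layers(contribs["surface"], contribs["deep"])
        report["stages"]["sources"]["anthropogenic_delta"] = \
            delta.round(1).to_dict()

    _write_json(out / "report.json", report)
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = [f"# soilmetal run report", "",
             f"- tool version: {report['tool_version']}",
             f"- config hash: {report['config_hash']}",
             f"- master seed: {report['seeds']['master']}", ""]
    stages = report["stages"]
    if "risk" in stages:
        lines += ["## Health risk (Monte Carlo means vs thresholds)", ""]
        for key, s in stages["risk"]["summary"].items():
            lines.append(
                f"- {key}: HI {s['HI_mean']:.3g} "
                f"({'>' if s['HI_exceeds'] else '<='} 1.0), "
                f"TCR {s['TCR_mean']:.3g} "
                f"({'>' if s['TCR_exceeds'] else '<='} 1e-4)")
        lines.append("")
    if "sources" in stages:
        lines += ["## Source apportionment (anthropogenic %, PMF)", ""]
        for lay in LAYERS:
            if lay in stages["sources"]:
                lines.append(f"- {lay}: "
                             f"{stages['sources'][lay]['anthropogenic_percent']}")
        if "anthropogenic_delta" in stages["sources"]:
            lines.append(f"- deep - surface delta: "
                         f"{stages['sources']['anthropogenic_delta']}")
        lines.append("")
    return "\n".join(lines)
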