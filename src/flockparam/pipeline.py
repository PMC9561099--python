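"""Orchestration: derive -> design -> fit -> report for trait panels.

Runs the univariate repeatability animal model over a panel of traits and
bivariate models over trait pairs, producing summary tables in the layout
genetic-parameter papers print: per trait the record counts, raw mean and
SD, model-based phenotypic SD, h2 (SE) and repeatability (SE); per pair
r_g (SE) and r_p (SE) with a star marking significance at the 5% level.
Univariate estimates seed the bivariate starting values.  Non-convergent
fits are flagged in the output and the run continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_design import DesignSet, ModelSpec, build_design
from .pedigree import Pedigree, read_pedigree
from .reml import FitResult, fit_bivariate, fit_univariate, significance


@dataclass
class TraitModel:
    """One panel entry: which table the trait lives in, and its model."""

    table: str
    spec: ModelSpec


@dataclass
class AnalysisConfig:
    """Panel definition: pedigree, phenotype tables, per-trait models, pairs."""

    pedigree: Pedigree
    tables: dict[str, pd.DataFrame]
    models: dict[str, TraitModel]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            for t in (a, b):
                if t not in self.models:
                    raise ValueError(f"pair trait {t!r} missing from the trait panel")
        for t, m in self.models.items():
            if m.table not in self.tables:
                raise ValueError(f"trait {t!r} references unknown table {m.table!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a declarative run config (paths resolved relative to the file)."""
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        base = path.parent
        ped = read_pedigree(base / cfg["pedigree"])
        tables = {
            name: pd.read_csv(base / p, na_values=["NA"])
            for name, p in cfg["tables"].items()
        }
        models = {}
        for trait, mc in cfg["models"].items():
            mc = dict(mc)
            table = mc.pop("table")
            models[trait] = TraitModel(table, ModelSpec.from_dict(mc))
        return cls(
            pedigree=ped,
            tables=tables,
            models=models,
            pairs=[tuple(p) for p in cfg.get("pairs", [])],
            alpha=float(cfg.get("alpha", 0.05)),
            out_dir=Path(cfg["out_dir"]) if "out_dir" in cfg else None,
        )


@dataclass
class PanelResult:
    """Summary table plus the underlying fits (reused as bivariate seeds)."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)
    designs: dict = field(default_factory=dict)


def _fit_one(config: AnalysisConfig, trait: str) -> tuple[DesignSet, FitResult]:
    tm = config.models[trait]
    design = build_design(config.tables[tm.table], tm.spec, config.pedigree)
    fit = fit_univariate(design, config.pedigree)
    return design, fit


def run_univariate_panel(config: AnalysisConfig) -> PanelResult:
    """Fit every trait in the panel; one summary row per trait.

    Columns: animal and record counts, raw mean and SD, the model-based
    phenotypic SD sigma_p = sqrt(sum of variance components) — at most the
    raw SD when fixed effects explain variance — then h2 (SE) and
    repeatability (SE, empty for single-record traits).
    """
    rows = []
    fits: dict[str, FitResult] = {}
    designs: dict[str, DesignSet] = {}
    for trait in config.models:
        try:
            design, fit = _fit_one(config, trait)
        except Exception as exc:  # a broken trait must not sink the panel
            rows.append({"trait": trait, "error": str(exc)})
            continue
        designs[trait] = design
        fits[trait] = fit
        comp = fit.components
        rows.append(
            {
                "trait": trait,
                "n_animals": int(pd.unique(design.animals).size),
                "n_records": design.n_records,
                "mean": float(np.mean(design.y)),
                "sd": float(np.std(design.y, ddof=1)),
                "sigma_p": float(np.sqrt(comp.phenotypic())),
                "h2": fit.h2,
                "h2_se": fit.h2_se,
                "repeatability": fit.repeatability,
                "repeatability_se": fit.repeatability_se,
                "converged": fit.converged,
                "boundary": fit.boundary,
            }
        )
    table = pd.DataFrame(rows)
    result = PanelResult(table=table, fits=fits, designs=designs)
    if config.out_dir is not None:
        _write_outputs(config, table, "univariate")
    return result


def run_bivariate_panel(
    config: AnalysisConfig, univariate: PanelResult | None = None
) -> PanelResult:
    """Fit every trait pair; r_g and r_p (SE) with significance stars.

    Univariate results, when given, seed the starting values (standard
    practice; faster and more robust convergence).
    """
    if univariate is None:
        univariate = run_univariate_panel(config)
    rows = []
    fits = {}
    for a, b in config.pairs:
        try:
            da = univariate.designs.get(a)
            db = univariate.designs.get(b)
            if da is None:
                da, _ = _fit_one(config, a)
            if db is None:
                db, _ = _fit_one(config, b)
            init = None
            if a in univariate.fits and b in univariate.fits:
                init = (univariate.fits[a], univariate.fits[b])
            fit = fit_bivariate(da, db, config.pedigree, init=init)
        except Exception as exc:
            rows.append({"trait_a": a, "trait_b": b, "error": str(exc)})
            continue
        fits[(a, b)] = fit
        rows.append(
            {
                "trait_a": a,
                "trait_b": b,
                "r_g": fit.r_g,
                "r_g_se": fit.r_g_se,
                "r_g_sig": significance(fit.r_g, fit.r_g_se, config.alpha)
                if fit.r_g is not None
                else None,
                "r_p": fit.r_p,
                "r_p_se": fit.r_p_se,
                "r_p_sig": significance(fit.r_p, fit.r_p_se, config.alpha)
                if fit.r_p is not None
                else None,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    result = PanelResult(table=table, fits=fits)
    if config.out_dir is not None:
        _write_outputs(config, table, "bivariate")
    return result


def format_estimate(est: float | None, se: float | None, star: bool = False) -> str:
    if est is None or (isinstance(est, float) and np.isnan(est)):
        return "NA"
    s = f"{est:.2f} ({se:.2f})" if se is not None else f"{est:.2f}"
    return s + ("*" if star else "")


def format_univariate_table(table: pd.DataFrame) -> str:
    """Pretty per-trait summary (mean, SD, sigma_p, h2, repeatability)."""
    lines = [
        f"{'Trait':<12} {'Animals':>8} {'Records':>8} {'Mean':>8} {'SD':>7} "
        f"{'sigma_p':>8} {'h2 (SE)':>14} {'Repeat (SE)':>14}"
    ]
    for row in table.itertuples():
        if getattr(row, "error", None) and isinstance(getattr(row, "error", None), str):
            lines.append(f"{row.trait:<12} failed: {row.error}")
            continue
        rep = format_estimate(row.repeatability, row.repeatability_se)
        lines.append(
            f"{row.trait:<12} {row.n_animals:>8} {row.n_records:>8} "
            f"{row.mean:>8.2f} {row.sd:>7.2f} {row.sigma_p:>8.2f} "
            f"{format_estimate(row.h2, row.h2_se):>14} {rep:>14}"
        )
    return "\n".join(lines)


def format_correlation_table(table: pd.DataFrame) -> str:
    """Pairs as rows: r_g (SE) and r_p (SE), starred at the chosen level."""
    lines = [f"{'Pair':<28} {'r_g (SE)':>16} {'r_p (SE)':>16}"]
    for row in table.itertuples():
        if getattr(row, "error", None) and isinstance(getattr(row, "error", None), str):
            lines.append(f"{row.trait_a} x {row.trait_b:<12} failed: {row.error}")
            continue
        pair = f"{row.trait_a} x {row.trait_b}"
        lines.append(
            f"{pair:<28} {format_estimate(row.r_g, row.r_g_se, bool(row.r_g_sig)):>16} "
            f"{format_estimate(row.r_p, row.r_p_se, bool(row.r_p_sig)):>16}"
        )
    return "\n".join(lines)


def _write_outputs(config: AnalysisConfig, table: pd.DataFrame, kind: str) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{kind}_panel.csv", index=False, na_rep="NA")
    fmt = format_univariate_table if kind == "univariate" else format_correlation_table
    (out / f"{kind}_panel.txt").write_text(fmt(table) + "\n")
    from . import __version__ as version

    manifest = {
        "flockparam_version": version,
        "kind": kind,
        "traits": list(config.models),
        "pairs": [list(p) for p in config.pairs],
        "alpha": config.alpha,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
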