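"""End-to-end orchestration: raw inputs to allometry, signal and correlate
reports.

A run is a pure function of (input files, config, seeds).  The config is a
YAML mapping with an ``inputs`` section (tree, traits, and either traces or a
precomputed SMR table), an ``options`` section (q10, reference temperature,
hypoxia fraction, lambda mode, alpha_stay, permutation count, seed) and an
``output_dir``.  Outputs: smr_table.csv, allometry_report.json,
signal_stats.json, residuals.csv, correlates.csv.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlates as corr
from . import io as sio
from .allometry import compare_models, fit_ols, fit_pgls, isometry_test
from .phylo_signal import phylo_signal, vcv_from_tree
from .respirometry import process_traces
from .trees import read_newick, resolve_polytomies

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_OPTIONS"]

log = logging.getLogger("seedsmr")

DEFAULT_OPTIONS = {
    "q10": 2.5,
    "t_ref": 20.0,
    "smoothing_window": 3,
    "hypoxia_frac": 0.8,
    "outlier_k": 2.0,
    "lambda_mode": "ML",
    "alpha_stay": 0.05,
    "n_perm": 999,
    "seed": 0,
    "resolve_polytomy_offset": 1.0,
    "climate_order": ["Csa", "BSh", "BWh"],
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_config(config_path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise PipelineError("config", f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text()) or {}
    cfg.setdefault("inputs", {})
    opts = dict(DEFAULT_OPTIONS)
    opts.update(cfg.get("options") or {})
    cfg["options"] = opts
    cfg.setdefault("output_dir", "seedsmr_results")
    return cfg


def _require_file(stage: str, path_str: str | None, what: str) -> Path:
    if not path_str:
        raise PipelineError(stage, f"config does not name a {what} file")
    path = Path(path_str)
    if not path.exists():
        raise PipelineError(stage, f"{what} file not found: {path}")
    return path


def run_pipeline(config_path) -> dict:
    """Execute the full analysis described by a YAML config.

    Returns a dict of the in-memory results (fits, stats tables) and writes
    the tidy outputs into ``output_dir``.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    cfg = _load_config(config_path)
    opts = cfg["options"]
    log.info("options: %s", json.dumps(opts, default=str))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    # --- tree ------------------------------------------------------------
    tree_path = _require_file("tree", cfg["inputs"].get("tree"), "tree")
    try:
        tree = read_newick(str(tree_path))
    except Exception as exc:
        raise PipelineError("tree", str(exc)) from exc
    if not tree.is_binary():
        log.info("tree has polytomies; resolving with %.3g Myr offsets",
                 opts["resolve_polytomy_offset"])
        tree = resolve_polytomies(tree, opts["resolve_polytomy_offset"])

    # --- traits ----------------------------------------------------------
    traits_path = _require_file("traits", cfg["inputs"].get("traits"), "trait table")
    try:
        traits = sio.read_trait_table(traits_path, tree=tree)
    except Exception as exc:
        raise PipelineError("traits", str(exc)) from exc

    # --- germination ------------------------------------------------------
    germ_path = cfg["inputs"].get("germination")
    if germ_path:
        germ_path = _require_file("germination", germ_path, "germination table")
        from .germination import GerminationFitError, fit_log_logistic

        try:
            germ = pd.read_csv(germ_path)
            fits = []
            for species, grp in germ.groupby("species"):
                try:
                    curve = fit_log_logistic(grp["time_days"], grp["cum_germ_pct"])
                    fits.append(
                        {"species": species, "t50_days": curve.t50,
                         "gmax_fit_pct": curve.gmax}
                    )
                except GerminationFitError:
                    fits.append({"species": species, "t50_days": np.nan,
                                 "gmax_fit_pct": np.nan})
            germ_fits = pd.DataFrame(fits)
            traits = traits.merge(germ_fits, on="species", how="left")
            if "gmax_pct" not in traits.columns:
                traits["gmax_pct"] = traits["gmax_fit_pct"]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("germination", str(exc)) from exc

    # --- respirometry ----------------------------------------------------
    traces_path = cfg["inputs"].get("traces")
    if traces_path:
        traces_path = _require_file("respirometry", traces_path, "trace table")
        try:
            traces = sio.read_traces(traces_path)
            smr_table = process_traces(
                traces,
                window=opts["smoothing_window"],
                hypoxia_frac=opts["hypoxia_frac"],
                outlier_k=opts["outlier_k"],
                t_ref=opts["t_ref"],
                q10=opts["q10"],
            )
        except Exception as exc:
            raise PipelineError("respirometry", str(exc)) from exc
    elif "smr20" in traits.columns:
        smr_table = traits[["species", "smr20"]].copy()
    else:
        raise PipelineError(
            "respirometry", "config needs either traces or a traits smr20 column"
        )
    smr_table.to_csv(outdir / "smr_table.csv", index=False)

    data = traits.merge(smr_table[["species", "smr20"]], on="species", how="inner")
    dropped = len(traits) - len(data)
    if dropped:
        log.info("dropped %d species without SMR measurements", dropped)
    data = data[np.isfinite(data["smr20"]) & (data["smr20"] > 0)]
    if len(data) < 3:
        raise PipelineError("allometry", "fewer than 3 species with usable SMR")

    # --- allometry -------------------------------------------------------
    cov = vcv_from_tree(tree)
    keep = [t for t in cov.taxa if t in set(data["species"])]
    idx = [cov.taxa.index(t) for t in keep]
    sub = cov.matrix[np.ix_(idx, idx)]
    from .phylo_signal import PhyloCovariance

    cov = PhyloCovariance(sub, keep)
    data = data.set_index("species").loc[keep].reset_index()

    log_mass = pd.Series(
        np.log10(data["dry_mass_mg"].to_numpy()), index=data["species"]
    )
    log_smr = pd.Series(np.log10(data["smr20"].to_numpy()), index=data["species"])
    try:
        ols = fit_ols(log_mass, log_smr)
        pgls = fit_pgls(
            log_mass, log_smr, cov,
            lambda_mode=opts["lambda_mode"],
            lam=opts.get("lambda"),
        )
    except Exception as exc:
        raise PipelineError("allometry", str(exc)) from exc
    t_iso, p_iso = isometry_test(ols)
    # model comparison needs ML likelihoods: re-profile lambda at ML when the
    # coefficient fit used REML
    if opts["lambda_mode"] == "ML":
        pgls_ml = fit_pgls(log_mass, log_smr, cov, lambda_mode="ML", reml=False)
    else:
        pgls_ml = pgls
    comparison = compare_models(ols, pgls_ml)

    def fit_report(fit):
        return {
            "method": fit.method,
            "intercept": fit.intercept,
            "coef_a": fit.coef_a,
            "slope": fit.slope,
            "se_intercept": fit.se_intercept,
            "se_slope": fit.se_slope,
            "t_slope": fit.t_slope,
            "lambda": fit.lam,
            "loglik_ml": fit.loglik_ml,
            "aic": fit.aic,
            "r2": fit.r2,
            "n": fit.n,
        }

    allometry_report = {
        "ols": fit_report(ols),
        "pgls": fit_report(pgls),
        "isometry_test": {"t": t_iso, "df": ols.df_resid, "p": p_iso},
        "comparison": comparison,
    }
    (outdir / "allometry_report.json").write_text(
        json.dumps(allometry_report, indent=2)
    )

    residuals = pgls.residuals.rename("residual")
    residuals.rename_axis("species").reset_index().to_csv(
        outdir / "residuals.csv", index=False
    )

    # --- phylogenetic signal ---------------------------------------------
    try:
        signal = {
            "log10_mass": phylo_signal(
                log_mass, cov, "log10_mass", n_perm=opts["n_perm"],
                seed=opts["seed"],
            ).to_dict(),
            "log10_smr20": phylo_signal(
                log_smr, cov, "log10_smr20", n_perm=opts["n_perm"],
                seed=opts["seed"] + 1,
            ).to_dict(),
        }
    except Exception as exc:
        raise PipelineError("signal", str(exc)) from exc
    (outdir / "signal_stats.json").write_text(json.dumps(signal, indent=2))

    # --- correlates ------------------------------------------------------
    rows = []
    resid = residuals.to_numpy()

    def add_row(factor, n, slope=None, se=None, f=None, df1=None, df2=None, p=None):
        rows.append(
            {"factor": factor, "slope": slope, "se": se, "F": f,
             "df1": df1, "df2": df2, "p": p, "n": n}
        )

    try:
        if "gmax_pct" in data.columns and data["gmax_pct"].notna().sum() >= 3:
            r = corr.simple_regression(resid, data["gmax_pct"])
            add_row("gmax_pct", r.n, r.slope, r.se, r.f, r.df1, r.df2, r.p)
        if "t50_days" in data.columns and data["t50_days"].notna().sum() >= 3:
            r = corr.simple_regression(resid, data["t50_days"])
            add_row("t50_days", r.n, r.slope, r.se, r.f, r.df1, r.df2, r.p)
        if "status" in data.columns:
            crop = (data["status"] == "crop").astype(float)
            if 0 < crop.sum() < len(crop):
                r = corr.simple_regression(resid, crop)
                add_row("crop_vs_wild", r.n, r.slope, r.se, r.f, r.df1, r.df2, r.p)
        native = (
            data[data["status"] == "native"]
            if "status" in data.columns
            else data
        )
        native_resid = residuals.loc[native["species"]].to_numpy()
        if "climate_class" in native.columns and native["climate_class"].notna().any():
            classes = native["climate_class"]
            try:
                f, df1, df2, p = corr.climate_anova(native_resid, classes)
                add_row("climate_anova", df2 + df1 + 1, f=f, df1=df1, df2=df2, p=p)
            except ValueError as exc:
                log.info("climate ANOVA skipped: %s", exc)
            try:
                f, df2, p = corr.ordered_contrast(
                    native_resid, classes, opts["climate_order"]
                )
                add_row("climate_aridity_contrast", df2 + len(opts["climate_order"]),
                        f=f, df1=1, df2=df2, p=p)
            except ValueError as exc:
                log.info("ordered contrast skipped: %s", exc)
        bioclim_cols = [c for c in sio.BIOCLIM_VARS if c in native.columns]
        if bioclim_cols:
            panel = native[bioclim_cols]
            complete = panel.notna().all(axis=1).to_numpy()
            if complete.sum() > len(bioclim_cols) + 1:
                step = corr.backward_stepwise(
                    native_resid[complete],
                    panel.loc[complete],
                    alpha_stay=opts["alpha_stay"],
                )
                for _, term in step.retained.iterrows():
                    add_row(f"bioclim:{term['term']}", step.n, term["slope"],
                            term["se"], term["F"], term["df1"], term["df2"],
                            term["p"])
                log.info("stepwise dropped (in order): %s", step.dropped)
    except Exception as exc:
        raise PipelineError("correlates", str(exc)) from exc

    correlates_df = pd.DataFrame(rows)
    correlates_df.to_csv(outdir / "correlates.csv", index=False)

    return {
        "smr_table": smr_table,
        "ols": ols,
        "pgls": pgls,
        "allometry_report": allometry_report,
        "signal": signal,
        "residuals": residuals,
        "correlates": correlates_df,
        "log_mass": log_mass,
        "log_smr": log_smr,
        "output_dir": outdir,
    }


def plot_allometry(result: dict, path) -> None:
    """Diagnostic log-log scatter with both fitted regression lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ols, pgls = result["ols"], result["pgls"]
    lm, ls = result["log_mass"], result["log_smr"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(lm, ls, s=12, alpha=0.6, color="0.3")
    xs = np.linspace(float(lm.min()), float(lm.max()), 50)
    ax.plot(xs, ols.predict(xs), label=f"OLS b={ols.slope:.3f}")
    ax.plot(xs, pgls.predict(xs), label=f"PGLS b={pgls.slope:.3f}")
    ax.set_xlabel("log10 seed dry mass (mg)")
    ax.set_ylabel("log10 SMR20 (ul O2 seed$^{-1}$ h$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
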