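"""End-to-end pipeline: simulate -> qc -> score -> associate -> discriminate -> project.

Runs the whole case-control GRS analysis on two simulated populations (an
Afro-Caribbean-like case-control sample and a white, men-only NPHSII-like
sample) and writes paper-style report tables: cohort characteristics,
per-SNP QC, the cross-population RAF/GRS comparison, adjusted logistic OR
tables, quintile ORs, ROC AUCs with the paired test, and the projection
JSON.  A run manifest records the config, seed, package versions and a
sha256 digest of every output; identical config + seed reproduces every
table byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .panel import load_panel, grs14_subset, load_raf_table
from .simulate import (
    Cohort,
    BINARY_TCRFS,
    afro_caribbean_config,
    white_config,
    simulate_case_control,
)
from .io import (
    GenotypeTable,
    write_dosage_table,
    write_covariates,
    complete_case_filter,
)
from .qc import snp_qc, compare_populations, expected_grs_hwe
from .association import (
    TCRF_MODEL_COLUMNS,
    compute_grs,
    per_sd_standardize,
    fit_logistic,
    quintile_analysis,
    two_sample_t,
)
from .discrimination import roc_auc, compare_auc, project_risk_reduction

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "render_table", "cohort_characteristics"]

DEFAULT_CONFIG: dict = {
    "afro_caribbean": {
        "n_cases": 178,
        "n_controls": 359,
        "or_per_sd": 1.40,
        "missing_rate": 0.0,
    },
    "white": {
        "n_cases": 146,
        "n_controls": 1214,
        "or_per_sd": 1.27,
        "missing_rate": 0.0,
    },
    "sd_source": "sample",
}

_CHARACTERISTIC_ROWS = [
    ("age", "Age, y", "continuous"),
    ("sex", "Male sex, %", "binary"),
    ("hypertension", "Hypertension, %", "binary"),
    ("hypercholesterolemia", "Hypercholesterolemia, %", "binary"),
    ("diabetes", "Diabetes, %", "binary"),
    ("smoking", "Current smokers, %", "binary"),
    ("bmi", "BMI", "continuous"),
    ("obesity", "Obesity (BMI >= 30 kg/m2), %", "binary"),
]


def _validate_config(config: Mapping[str, Any]) -> dict:
    cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}; known: {sorted(cfg)}")
        if isinstance(val, dict):
            unknown = set(val) - set(cfg[key])
            if unknown:
                raise ValueError(f"unknown config key(s) {sorted(unknown)} under {key!r}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    for pop in ("afro_caribbean", "white"):
        if cfg[pop]["n_cases"] <= 0 or cfg[pop]["n_controls"] <= 0:
            raise ValueError(f"{pop}: n_cases and n_controls must be positive")
    return cfg


def cohort_characteristics(cohort: Cohort) -> pd.DataFrame:
    """Case-vs-control covariate summary (t test continuous, chi2 binary)."""
    from scipy import stats

    y = cohort.outcome.to_numpy(dtype=int)
    rows = []
    for col, label, kind in _CHARACTERISTIC_ROWS:
        if col not in cohort.covariates.columns:
            continue
        x = cohort.covariates[col].to_numpy(dtype=float)
        cases, controls = x[y == 1], x[y == 0]
        if kind == "continuous":
            t, _, p = two_sample_t(cases, controls)
            rows.append(
                (label, np.mean(cases), np.std(cases, ddof=1),
                 np.mean(controls), np.std(controls, ddof=1), p)
            )
        else:
            tbl = np.array(
                [[cases.sum(), len(cases) - cases.sum()],
                 [controls.sum(), len(controls) - controls.sum()]]
            )
            if tbl[:, 0].sum() in (0, tbl.sum()):
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(tbl, correction=False)
            rows.append(
                (label, 100 * np.mean(cases), np.nan, 100 * np.mean(controls), np.nan, p)
            )
    return pd.DataFrame(
        rows, columns=["variable", "cases_value", "cases_sd", "controls_value",
                       "controls_sd", "p"]
    ).set_index("variable")


def _fmt(x: float, nd: int = 2) -> str:
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.{nd}f}"


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    if p < 1e-3:
        return f"{p:.1e}"
    return f"{p:.3f}"


def render_table(result: pd.DataFrame, style: str) -> str:
    """Render a stage result as a paper-style TSV string.

    Styles: ``table2`` (cohort characteristics), ``table3`` (per-SNP RAF
    comparison + GRS rows), ``table4`` (logistic OR table), ``quintiles``.
    Numbers are formatted at the printed precision of the corresponding
    published tables; machine-readable outputs keep full precision.
    """
    if style == "table2":
        lines = ["variable\tcases\tcontrols\tp"]
        for label, row in result.iterrows():
            if np.isfinite(row["cases_sd"]):
                c = f"{_fmt(row['cases_value'])} (± {_fmt(row['cases_sd'])})"
                k = f"{_fmt(row['controls_value'])} (± {_fmt(row['controls_sd'])})"
            else:
                c, k = _fmt(row["cases_value"], 1), _fmt(row["controls_value"], 1)
            lines.append(f"{label}\t{c}\t{k}\t{_fmt_p(row['p'])}")
        return "\n".join(lines) + "\n"
    if style == "table3":
        cols = list(result.columns)
        lines = ["\t".join(["row", *cols])]
        for label, row in result.iterrows():
            vals = [
                _fmt_p(v) if c == "p" else _fmt(v, 2)
                for c, v in zip(cols, row)
            ]
            lines.append("\t".join([str(label), *vals]))
        return "\n".join(lines) + "\n"
    if style == "table4":
        lines = ["term\tor\tci95\tp"]
        for term, row in result.iterrows():
            if term == "intercept":
                continue
            lines.append(
                f"{term}\t{_fmt(row['or'])}\t({_fmt(row['ci_low'])}-"
                f"{_fmt(row['ci_high'])})\t{_fmt_p(row['p'])}"
            )
        return "\n".join(lines) + "\n"
    if style == "quintiles":
        lines = ["quintile\tn_cases\tn_controls\tcontrol_pct\tor\tci95\tp"]
        for q, row in result.iterrows():
            ci = ("reference" if not np.isfinite(row["ci_low"])
                  else f"({_fmt(row['ci_low'])}-{_fmt(row['ci_high'])})")
            lines.append(
                f"Q{q}\t{int(row['n_cases'])}\t{int(row['n_controls'])}\t"
                f"{_fmt(100 * row['control_fraction'], 1)}\t{_fmt(row['or'])}\t{ci}\t"
                f"{_fmt_p(row['p'])}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(
        f"unknown style {style!r}; available: table2, table3, table4, quintiles"
    )


def _grs_frame(cohort: Cohort, panel19, panel14) -> pd.DataFrame:
    table = GenotypeTable(cohort.genotypes)
    return pd.DataFrame(
        {
            "grs19": compute_grs(table, panel19, weighted=False).values,
            "grs14": compute_grs(table, panel14, weighted=False).values,
            "wgrs19": compute_grs(table, panel19, weighted=True).values,
            "wgrs14": compute_grs(table, panel14, weighted=True).values,
            "chd": cohort.outcome,
        }
    )


def _adjusted_grs_fit(cohort: Cohort, scores: pd.Series, sd_source: str,
                      covariate_cols: list[str]):
    from .association import GrsVector

    grs = GrsVector(values=scores, panel_name="", weighted=False)
    std = per_sd_standardize(grs, sd_source=sd_source,
                             controls=(cohort.outcome == 0))
    X = cohort.covariates[covariate_cols].copy()
    X["grs"] = std
    return fit_logistic(cohort.outcome, X)


def run_pipeline(config: Mapping[str, Any] | None, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute every stage and write the report bundle plus a manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage
    name in the exception; outputs of completed stages are preserved.
    """
    cfg = _validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel19 = load_panel("grs19")
    panel14 = grs14_subset(panel19)
    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "versions": {
            "cardiogrs": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage: str, files: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in files.items()
        }

    stage = "simulate"
    try:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        afro_cfg = afro_caribbean_config(seed=seeds[0], panel=panel19,
                                         or_per_sd=cfg["afro_caribbean"]["or_per_sd"],
                                         missing_rate=cfg["afro_caribbean"]["missing_rate"])
        afro_cfg.n_cases = cfg["afro_caribbean"]["n_cases"]
        afro_cfg.n_controls = cfg["afro_caribbean"]["n_controls"]
        white_cfg = white_config(seed=seeds[1], panel=panel19,
                                 or_per_sd=cfg["white"]["or_per_sd"],
                                 missing_rate=cfg["white"]["missing_rate"])
        white_cfg.n_cases = cfg["white"]["n_cases"]
        white_cfg.n_controls = cfg["white"]["n_controls"]
        cohorts = {c.population: c for c in
                   (simulate_case_control(afro_cfg), simulate_case_control(white_cfg))}
        files = {}
        for name, cohort in cohorts.items():
            gpath = out / f"{name}.dosages.tsv"
            cpath = out / f"{name}.covariates.csv"
            write_dosage_table(GenotypeTable(cohort.genotypes), gpath)
            write_covariates(cohort, cpath)
            files[gpath.name], files[cpath.name] = gpath, cpath
        record(stage, files)

        stage = "qc"
        files = {}
        qc_tables = {}
        for name, cohort in cohorts.items():
            qdf = snp_qc(GenotypeTable(cohort.genotypes))
            qc_tables[name] = qdf
            p = out / f"qc_{name}.tsv"
            qdf.to_csv(p, sep="\t", float_format="%.6g")
            files[p.name] = p
        # cross-population comparison on controls, Table-3 style
        ctrl = {n: c.subset(c.outcome == 0) for n, c in cohorts.items()}
        raf_tbls = {}
        for name, cohort in ctrl.items():
            q = snp_qc(GenotypeTable(cohort.genotypes))
            raf_tbls[name] = pd.DataFrame(
                {"raf": q["raf"], "n_individuals": q[["n0", "n1", "n2"]].sum(axis=1)}
            )
        comparison = compare_populations(
            raf_tbls["afro_caribbean"], raf_tbls["white_nphsii"],
            label_a="afro_caribbean", label_b="white",
        )
        # GRS summary rows (complete-case controls)
        cc_ctrl = {n: complete_case_filter(c) if c.genotypes.isna().any().any() else c
                   for n, c in ctrl.items()}
        grs_rows = []
        for pname, pan in (("Nonweighted GRS19", panel19), ("Nonweighted GRS14", panel14)):
            g = {n: compute_grs(GenotypeTable(c.genotypes), pan).values
                 for n, c in cc_ctrl.items()}
            a, w = g["afro_caribbean"], g["white_nphsii"]
            _, _, p = two_sample_t(a, w)
            grs_rows.append((pname, a.mean(), w.mean(), np.nan, p))
        comp_out = comparison.reset_index().rename(columns={"rsid": "row"}).set_index("row")
        comp_out = pd.concat([
            comp_out,
            pd.DataFrame(grs_rows, columns=["row", "raf_afro_caribbean", "raf_white",
                                            "chi2", "p"]).set_index("row"),
        ])
        p = out / "raf_comparison.tsv"
        comp_out.to_csv(p, sep="\t", float_format="%.6g")
        files[p.name] = p
        p = out / "table3_raf_comparison.txt"
        p.write_text(render_table(comp_out, "table3"))
        files[p.name] = p
        record(stage, files)

        stage = "score"
        files = {}
        cc = {n: complete_case_filter(c) if c.genotypes.isna().any().any() else c
              for n, c in cohorts.items()}
        grs_frames = {n: _grs_frame(c, panel19, panel14) for n, c in cc.items()}
        for name, frame in grs_frames.items():
            p = out / f"grs_{name}.tsv"
            frame.to_csv(p, sep="\t", float_format="%.6g")
            files[p.name] = p
        record(stage, files)

        stage = "associate"
        files = {}
        afro = cc["afro_caribbean"]
        chars = cohort_characteristics(afro)
        p = out / "table2_characteristics.tsv"
        chars.to_csv(p, sep="\t", float_format="%.6g")
        files[p.name] = p
        (out / "table2_characteristics.txt").write_text(render_table(chars, "table2"))
        files["table2_characteristics.txt"] = out / "table2_characteristics.txt"

        sd_source = cfg["sd_source"]
        fit19 = _adjusted_grs_fit(afro, grs_frames["afro_caribbean"]["grs19"],
                                  sd_source, TCRF_MODEL_COLUMNS)
        p = out / "table4_adjusted_model.tsv"
        fit19.terms.to_csv(p, sep="\t", float_format="%.6g")
        files[p.name] = p
        (out / "table4_adjusted_model.txt").write_text(render_table(fit19.terms, "table4"))
        files["table4_adjusted_model.txt"] = out / "table4_adjusted_model.txt"

        rows = []
        fits = {}
        for col in ("grs19", "wgrs19", "grs14", "wgrs14"):
            f = _adjusted_grs_fit(afro, grs_frames["afro_caribbean"][col],
                                  sd_source, TCRF_MODEL_COLUMNS)
            fits[col] = f
            r = f.terms.loc["grs"]
            rows.append((col, r["or"], r["ci_low"], r["ci_high"], r["p"]))
        table5 = pd.DataFrame(
            rows, columns=["score", "or", "ci_low", "ci_high", "p"]
        ).set_index("score")
        p = out / "table5_grs_models.tsv"
        table5.to_csv(p, sep="\t", float_format="%.6g")
        files[p.name] = p

        # men-only comparison across populations (white sample is men-only)
        men = afro.subset(afro.covariates["sex"] == 1)
        men_cols = [c for c in TCRF_MODEL_COLUMNS if c != "sex"]
        rows = []
        men_grs = {n: None for n in cc}
        for pop_name, cohort in (("afro_caribbean", men), ("white_nphsii", cc["white_nphsii"])):
            frame = _grs_frame(cohort, panel19, panel14)
            men_grs[pop_name] = frame
            for col in ("grs19", "wgrs19", "grs14", "wgrs14"):
                f = _adjusted_grs_fit(cohort, frame[col], sd_source, men_cols)
                r = f.terms.loc["grs"]
                rows.append((pop_name, col, r["or"], r["ci_low"], r["ci_high"], r["p"]))
        table6 = pd.DataFrame(
            rows, columns=["population", "score", "or", "ci_low", "ci_high", "p"]
        ).set_index(["population", "score"])
        p = out / "table6_men_only.tsv"
        table6.to_csv(p, sep="\t", float_format="%.6g")
        files[p.name] = p

        from .association import GrsVector

        for col in ("grs19", "grs14"):
            g = GrsVector(grs_frames["afro_caribbean"][col], col, False)
            qres = quintile_analysis(g, afro.outcome, afro.covariates[TCRF_MODEL_COLUMNS])
            p = out / f"quintiles_{col}.tsv"
            qres.table.to_csv(p, sep="\t", float_format="%.6g")
            files[p.name] = p
            (out / f"quintiles_{col}.txt").write_text(render_table(qres.table, "quintiles"))
            files[f"quintiles_{col}.txt"] = out / f"quintiles_{col}.txt"
        record(stage, files)

        stage = "discriminate"
        files = {}
        X_tcrf = afro.covariates[TCRF_MODEL_COLUMNS]
        fit_tcrf = fit_logistic(afro.outcome, X_tcrf)
        probs = {}
        const = np.ones(len(afro.outcome))
        Xc = np.column_stack([const, X_tcrf.to_numpy(dtype=float)])
        from scipy.special import expit as _expit

        probs["tcrf"] = _expit(Xc @ fit_tcrf.terms["coef"].to_numpy())
        aucs = {"tcrf": roc_auc(probs["tcrf"], afro.outcome, "TCRF")}
        auc_json = {}
        for col in ("grs14", "grs19"):
            Xg = X_tcrf.copy()
            Xg["grs"] = grs_frames["afro_caribbean"][col]
            fg = fit_logistic(afro.outcome, Xg)
            pr = _expit(
                np.column_stack([const, Xg.to_numpy(dtype=float)])
                @ fg.terms["coef"].to_numpy()
            )
            probs[f"tcrf+{col}"] = pr
            aucs[f"tcrf+{col}"] = roc_auc(pr, afro.outcome, f"TCRF+{col}")
            cmpres = compare_auc(pr, probs["tcrf"], afro.outcome)
            auc_json[col] = {
                "auc_tcrf": aucs["tcrf"].auc,
                "auc_tcrf_se": aucs["tcrf"].se,
                "auc_with_grs": aucs[f"tcrf+{col}"].auc,
                "auc_with_grs_se": aucs[f"tcrf+{col}"].se,
                "delong_p": cmpres["p"],
            }
        p = out / "roc_auc.json"
        p.write_text(json.dumps(auc_json, indent=2, sort_keys=True))
        files[p.name] = p
        record(stage, files)

        stage = "project"
        files = {}
        proj: dict = {}
        for col, pan in (("grs19", panel19), ("grs14", panel14)):
            mean_a = float(men_grs["afro_caribbean"][col].mean())
            mean_b = float(men_grs["white_nphsii"][col].mean())
            sd_b = float(men_grs["white_nphsii"][col].std(ddof=1))
            # per-SD OR from the men-only adjusted model of the lower-GRS population
            or_per_sd = float(table6.loc[("afro_caribbean", col), "or"])
            res = project_risk_reduction(
                grs_mean_a=mean_a, grs_mean_b=mean_b,
                or_per_sd=or_per_sd, sd=sd_b, method="both",
            )
            proj[col] = {
                r.method: {"relative_risk_reduction": r.relative_risk_reduction,
                           "delta_grs": r.delta_grs, "inputs": r.inputs_record}
                for r in res
            }
        p = out / "projection.json"
        p.write_text(json.dumps(proj, indent=2, sort_keys=True))
        files[p.name] = p
        record(stage, files)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stages, outputs in %s", len(manifest["stages"]), out)
    return manifest
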