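"""End-to-end pipeline: read responses, fit, simulate the adaptive test,
classify, and audit fairness — with all artifacts written to disk.

The pipeline mirrors how such a screening evaluation is actually run:
calibrate the item bank on the full-length responses, replay every
patient through the adaptive test, map the resulting trait estimates
back to the 0-30 scale, compare the implied screen against the
full-length classification, and test the false-negative rate for
homogeneity across demographic groups.

Everything is driven by one :class:`PipelineConfig`; given the same
config and input the run is deterministic.  Figures are optional
presentation artifacts — every number plotted is also emitted as
CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .cat import CATConfig, simulate_cohort
from .estimate import fit_grm
from .grm import ItemBank, LatentModel
from .synth import CohortSpec, generate_cohort

logger = logging.getLogger("epdscat")

__all__ = ["PipelineConfig", "read_response_table", "write_response_table", "run_pipeline"]

ITEM_COLUMNS = [f"item{i}" for i in range(1, 11)]


def read_response_table(path, *, strict: bool = True, n_categories: int = 4) -> pd.DataFrame:
    """Read and validate a patient-level response CSV.

    Requires columns ``item1..item10`` (integers in 0..3) and accepts
    ``race`` (missing values mapped to "Unknown") and ``age``.  In
    strict mode an out-of-range or missing item response raises with the
    offending row and item; in lenient mode such rows are dropped with a
    log message.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    items = df[ITEM_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = items.isna() | (items < 0) | (items > n_categories - 1) | (items % 1 != 0)
    if bad.to_numpy().any():
        rows = np.where(bad.any(axis=1))[0]
        first_row = int(rows[0])
        first_item = bad.columns[np.where(bad.iloc[first_row])[0][0]]
        msg = (
            f"invalid response at row {first_row + 2} (1-based, incl. header), "
            f"column {first_item}"
        )
        if strict:
            raise ValueError(msg)
        logger.warning("%s; dropping %d invalid rows", msg, len(rows))
        df = df.drop(index=df.index[rows]).reset_index(drop=True)
        items = df[ITEM_COLUMNS]
    df[ITEM_COLUMNS] = items.astype(int)
    if "race" not in df.columns:
        df["race"] = "Unknown"
    df["race"] = df["race"].fillna("Unknown").astype(str)
    return df


def write_response_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """One config drives the whole run; validated before any stage executes."""

    output_dir: str | Path = "pipeline_out"
    input_csv: str | Path | None = None  # if None, synthesize a cohort
    synth_n: int = 2000
    dimension: int = 1
    seed: int = 0
    bank_csv: str | Path | None = None  # skip fitting if given
    moderate_cutoff: int = 8
    high_cutoff: int = 13
    reference_group: str = "White"
    termination_delta: float = 0.05
    min_items: int = 2
    max_items: int | None = None
    si_always_administered: bool = False
    shrinkage_correction: bool = True
    fit_tol: float = 1e-4
    fit_max_cycles: int = 500
    make_plots: bool = True
    extra_cat: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.moderate_cutoff <= self.high_cutoff <= 30):
            raise ValueError("cutoffs must satisfy 0 < moderate <= high <= 30")
        if self.dimension not in (1, 2, 3):
            raise ValueError("dimension must be 1, 2 or 3")
        if self.termination_delta <= 0:
            raise ValueError("termination_delta must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls(**raw)

    def cat_config(self) -> CATConfig:
        return CATConfig(
            termination_delta=self.termination_delta,
            min_items=self.min_items,
            max_items=self.max_items,
            si_always_administered=self.si_always_administered,
            shrinkage_correction=self.shrinkage_correction,
            **self.extra_cat,
        )


def _jsonable(obj):
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute fit -> adaptive-test simulation -> scoring -> evaluation.

    Returns the report dictionary and writes, under ``output_dir``:
    the response table used, fitted bank (CSV + JSON), fit summary,
    per-patient adaptive-test results, metrics JSON, fairness report,
    a markdown report, and (optionally) the summary figures.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    logger.info("pipeline config: %s", dataclasses.asdict(config))

    # ---- stage: input
    if config.input_csv is not None:
        table = read_response_table(config.input_csv)
    else:
        spec = CohortSpec(n=config.synth_n, dimension=config.dimension, seed=config.seed)
        table = generate_cohort(spec)
        write_response_table(table, out / "synthetic_responses.csv")
    X = table[ITEM_COLUMNS].to_numpy(dtype=int)
    observed_totals = X.sum(axis=1)
    si = X[:, 9]

    # ---- stage: calibration
    if config.bank_csv is not None:
        bank = ItemBank.from_csv(config.bank_csv)
        latent = LatentModel(bank.dimension)
        fit_summary = {"source": str(config.bank_csv)}
    else:
        fit = fit_grm(
            X,
            config.dimension,
            tol=config.fit_tol,
            max_cycles=config.fit_max_cycles,
            n_categories=4,
            min_rows=min(200, X.shape[0]),
            on_empty_category="collapse",
        )
        bank, latent = fit.bank, fit.latent
        fit_summary = fit.summary()
    bank.to_csv(out / "bank.csv")
    bank.to_json(out / "bank.json")
    (out / "fit_summary.json").write_text(json.dumps(_jsonable(fit_summary), indent=2))

    # ---- stage: adaptive-test simulation + scoring
    results, summary = simulate_cohort(X, bank, latent, config.cat_config())
    predicted_totals = np.array([r.expected_total for r in results])
    n_items_admin = np.array([r.n_administered for r in results])
    per_patient = pd.DataFrame(
        {
            "n_items": n_items_admin,
            "items": [" ".join(str(i + 1) for i in r.administered) for r in results],
            "expected_total": predicted_totals,
            "observed_total": observed_totals,
            "si_response": si,
            "race": table["race"].to_numpy(),
        }
    )
    for d in range(bank.dimension):
        per_patient[f"theta{d + 1}"] = [r.final_estimate.theta_hat[d] for r in results]
        per_patient[f"se{d + 1}"] = [r.final_estimate.posterior_sd[d] for r in results]
        if results[0].final_estimate.corrected_theta is not None:
            per_patient[f"theta{d + 1}_corrected"] = [
                r.final_estimate.corrected_theta[d] for r in results
            ]
    per_patient.to_csv(out / "cat_results.csv", index=False)

    # ---- stage: evaluation
    truth = np.array(
        [
            ev.classify_full_test(t, s, config.moderate_cutoff, config.high_cutoff).positive
            for t, s in zip(observed_totals, si)
        ]
    )
    predicted = np.array(
        [
            ev.classify_cat_result(t, s, config.moderate_cutoff).positive
            for t, s in zip(predicted_totals, si)
        ]
    )
    alpha, alpha_ci = ev.cronbach_alpha(X)
    metrics = ev.diagnostic_metrics(truth, predicted)
    r, r_ci, r_p = ev.score_agreement(predicted_totals, observed_totals)
    fairness = ev.fnr_parity(truth, predicted, table["race"], config.reference_group)

    report = {
        "n_patients": int(X.shape[0]),
        "dimension": bank.dimension,
        "fit": _jsonable(fit_summary),
        "cronbach_alpha": alpha,
        "cronbach_alpha_ci": list(alpha_ci),
        "full_test_positive_rate": float(truth.mean()),
        "cat_positive_rate": float(predicted.mean()),
        "median_items": summary.median_items,
        "items_range": [summary.min_items, summary.max_items],
        "score_correlation": {"r": r, "ci": list(r_ci), "p": r_p},
        "diagnostics": _jsonable(metrics.as_dict()),
        "fairness": _jsonable(fairness.as_dict()),
        "config": _jsonable(dataclasses.asdict(config)),
    }
    (out / "metrics.json").write_text(json.dumps(_jsonable(report), indent=2))
    (out / "fairness.json").write_text(
        json.dumps(_jsonable(fairness.as_dict()), indent=2)
    )
    _write_markdown(report, out / "report.md")
    if config.make_plots:
        _make_plots(observed_totals, predicted_totals, n_items_admin, fairness, config, out)
    logger.info("pipeline complete: %s", out)
    return report


def _write_markdown(report: dict, path: Path) -> None:
    d = report["diagnostics"]

    def pct(x):
        return "undefined" if x is None else f"{100 * x:.1f}%"

    lines = [
        "# Adaptive-test screening evaluation",
        "",
        f"- patients: {report['n_patients']}",
        f"- factor model: {report['dimension']}-factor graded response model",
        f"- Cronbach's alpha: {report['cronbach_alpha']:.3f} "
        f"(95% CI {report['cronbach_alpha_ci'][0]:.3f}-{report['cronbach_alpha_ci'][1]:.3f})",
        f"- full-test positive-screen rate: {pct(report['full_test_positive_rate'])}",
        f"- adaptive-test positive rate: {pct(report['cat_positive_rate'])}",
        f"- median items administered: {report['median_items']:.0f} "
        f"(range {report['items_range'][0]}-{report['items_range'][1]})",
        f"- r(predicted, observed totals): {report['score_correlation']['r']:.3f} "
        f"(95% CI {report['score_correlation']['ci'][0]:.3f}-{report['score_correlation']['ci'][1]:.3f})",
        f"- NPV: {pct(d['npv'])}; PPV: {pct(d['ppv'])}; FNR: {pct(d['fnr'])}",
        "",
        "## FNR parity",
        "",
        f"chi-square({report['fairness']['df']}) = {report['fairness']['chi2']:.2f}, "
        f"p = {report['fairness']['p_value']:.3f} "
        f"(reference group: {report['fairness']['reference_group']})",
        "",
        "| group | FN | TP | FNR | parity ratio |",
        "|---|---|---|---|---|",
    ]
    f = report["fairness"]
    for g in f["groups"]:
        ratio = f["parity_ratio"][g]
        lines.append(
            f"| {g} | {f['fn'][g]} | {f['tp'][g]} | {f['fnr'][g]:.3f} | "
            + (f"{ratio:.2f} |" if ratio is not None else "undefined |")
        )
    path.write_text("\n".join(lines) + "\n")


def _make_plots(observed, predicted, n_items, fairness, config: PipelineConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax = axes[0, 0]
    ax.hist(observed, bins=np.arange(-0.5, 31.5), color="steelblue")
    ax.axvline(config.moderate_cutoff, color="black")
    ax.set_title("Observed full-test totals")
    ax = axes[0, 1]
    ax.hist(predicted, bins=np.arange(-0.5, 31.5), color="darkorange")
    ax.axvline(config.moderate_cutoff, color="black")
    ax.set_title("Predicted totals (adaptive test)")
    ax = axes[1, 0]
    ax.hist(n_items, bins=np.arange(0.5, 11.5), color="seagreen")
    ax.set_title("Items administered")
    ax = axes[1, 1]
    groups = fairness.groups
    ratios = [fairness.parity_ratio[g] or 0 for g in groups]
    ax.bar(range(len(groups)), ratios, color="indianred")
    ax.axhline(1.0, color="black", linestyle="--")
    ax.set_xticks(range(len(groups)), groups, rotation=45, ha="right")
    ax.set_title(f"FNR parity (ref: {fairness.reference_group})")
    fig.tight_layout()
    fig.savefig(out / "report_figures.png", dpi=120)
    plt.close(fig)
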