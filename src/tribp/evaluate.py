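"""Agreement metrics, Bland–Altman analysis and BHS grading.

Error conventions: differences are predicted minus reference.  The standard
deviation of error (SDE) and the Bland–Altman limits of agreement use the
population (1/N) standard deviation.  BHS grading computes the cumulative
percentage of absolute errors within 5/10/15 mmHg and assigns the best
grade whose three thresholds are all met, with inclusive boundaries:

    grade A: >= 60 / 85 / 95 %        grade B: >= 50 / 75 / 90 %
    grade C: >= 40 / 65 / 85 %        otherwise D.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Metrics",
    "EvalReport",
    "BHS_THRESHOLDS",
    "metrics",
    "bland_altman",
    "bhs_grade",
    "evaluate_predictions",
    "render_report",
]

BHS_THRESHOLDS = (
    ("A", (60.0, 85.0, 95.0)),
    ("B", (50.0, 75.0, 90.0)),
    ("C", (40.0, 65.0, 85.0)),
)


@dataclass
class Metrics:
    mae: float
    me: float
    sde: float
    pcc: float
    n: int


@dataclass
class EvalReport:
    """Agreement summary for one model/target pair."""

    model: str
    target: str
    mae: float
    me: float
    sde: float
    pcc: float
    mean_diff: float
    loa_low: float
    loa_high: float
    pct5: float
    pct10: float
    pct15: float
    grade: str
    n: int


def metrics(pred: np.ndarray, ref: np.ndarray) -> Metrics:
    """MAE, mean error, population SD of error and Pearson correlation.

    PCC is NaN ("missing") when either series has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("prediction/reference length mismatch")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = pred - ref
    mae = float(np.mean(np.abs(diff)))
    me = float(np.mean(diff))
    sde = float(np.std(diff))
    if np.std(pred) == 0.0 or np.std(ref) == 0.0:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(pred, ref)[0, 1])
    return Metrics(mae=mae, me=me, sde=sde, pcc=pcc, n=n)


def bland_altman(pred: np.ndarray, ref: np.ndarray
                 ) -> tuple[float, float, float]:
    """(mean difference, lower LoA, upper LoA); LoA = mean ± 1.96·SD."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(pred) < 2:
        raise ValueError("need at least two pairs")
    diff = pred - ref
    mean_diff = float(np.mean(diff))
    spread = 1.96 * float(np.std(diff))
    return mean_diff, mean_diff - spread, mean_diff + spread


def bhs_grade(abs_errors: np.ndarray) -> tuple[float, float, float, str]:
    """Cumulative |error| percentages at 5/10/15 mmHg and the BHS grade."""
    abs_errors = np.abs(np.asarray(abs_errors, dtype=float))
    if len(abs_errors) == 0:
        raise ValueError("empty error list")
    pct = tuple(float(100.0 * np.mean(abs_errors <= thr))
                for thr in (5.0, 10.0, 15.0))
    grade = "D"
    for name, mins in BHS_THRESHOLDS:
        if all(p >= m for p, m in zip(pct, mins)):
            grade = name
            break
    return pct[0], pct[1], pct[2], grade


def evaluate_predictions(pred_df: pd.DataFrame,
                         aggregate: str = "pooled") -> list[EvalReport]:
    """Build an EvalReport per (model, target) pair in a predictions table.

    ``aggregate='pooled'`` computes every statistic over all test segments
    at once; ``aggregate='per-subject'`` computes MAE/ME/SDE/PCC per subject
    and averages them (Bland–Altman and BHS remain pooled, as they describe
    the pooled error distribution).
    """
    if aggregate not in ("pooled", "per-subject"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    if len(pred_df) == 0:
        raise ValueError("empty prediction set")
    reports = []
    for (model, target), grp in pred_df.groupby(["model", "target"],
                                                sort=True):
        yp = grp["y_pred"].to_numpy(dtype=float)
        yt = grp["y_true"].to_numpy(dtype=float)
        if aggregate == "pooled":
            m = metrics(yp, yt)
        else:
            per = [metrics(g["y_pred"].to_numpy(), g["y_true"].to_numpy())
                   for _, g in grp.groupby("subject") if len(g) >= 2]
            m = Metrics(
                mae=float(np.mean([x.mae for x in per])),
                me=float(np.mean([x.me for x in per])),
                sde=float(np.mean([x.sde for x in per])),
                pcc=float(np.nanmean([x.pcc for x in per])),
                n=len(grp),
            )
        mean_diff, lo, hi = bland_altman(yp, yt)
        p5, p10, p15, grade = bhs_grade(yp - yt)
        reports.append(EvalReport(
            model=str(model), target=str(target),
            mae=m.mae, me=m.me, sde=m.sde, pcc=m.pcc,
            mean_diff=mean_diff, loa_low=lo, loa_high=hi,
            pct5=p5, pct10=p10, pct15=p15, grade=grade, n=m.n,
        ))
    return reports


def render_report(reports: list[EvalReport], out_dir: str | Path,
                  pred_df: pd.DataFrame | None = None,
                  plots: bool = True) -> dict[str, Path]:
    """Write the metrics CSV (and agreement plots) to ``out_dir``.

    File names are deterministic; reruns on identical inputs produce an
    identical CSV.
    """
    if not reports:
        raise ValueError("empty report list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([asdict(r) for r in reports])
    csv_path = out_dir / "metrics.csv"
    df.to_csv(csv_path, index=False, float_format="%.6g")
    paths = {"metrics": csv_path}
    if plots and pred_df is not None and len(pred_df):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for (model, target), grp in pred_df.groupby(["model", "target"]):
            yp = grp["y_pred"].to_numpy(dtype=float)
            yt = grp["y_true"].to_numpy(dtype=float)
            tag = f"{model}_{target}"
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            axes[0].scatter(yt, yp, s=8, alpha=0.5)
            lims = [min(yt.min(), yp.min()) - 2, max(yt.max(), yp.max()) + 2]
            axes[0].plot(lims, lims, "k--", lw=1)
            axes[0].set_xlabel(f"reference {target} (mmHg)")
            axes[0].set_ylabel(f"predicted {target} (mmHg)")
            axes[0].set_title("correlation")
            mean_diff, lo, hi = bland_altman(yp, yt)
            avg = (yp + yt) / 2.0
            axes[1].scatter(avg, yp - yt, s=8, alpha=0.5)
            for yline, style in ((mean_diff, "-"), (lo, "--"), (hi, "--")):
                axes[1].axhline(yline, color="r", ls=style, lw=1)
            axes[1].set_xlabel("mean of methods (mmHg)")
            axes[1].set_ylabel("difference (mmHg)")
            axes[1].set_title("Bland-Altman")
            fig.suptitle(tag)
            fig.tight_layout()
            p = out_dir / f"agreement_{tag}.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            paths[f"plot_{tag}"] = p
    return paths
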