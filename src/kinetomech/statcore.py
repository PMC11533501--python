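"""Shared statistics and the end-to-end pipeline runner.

The Kolmogorov-Smirnov comparison, mean/SEM and box summaries used by
every assay module live here, together with ``run_pipeline``, which
chains simulate -> analyze for each selected assay and writes tables, a
metrics JSON, and a log.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-15


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov result."""

    statistic: float  # D in [0, 1]
    pvalue: float
    n_a: int
    n_b: int
    method: str  # "exact" | "asymptotic"
    p_is_bound: bool = False  # True when pvalue was floored at P_FLOOR


def ks_two_sample(a, b) -> KSResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b| with p-value.

    The p-value is exact (conditional permutation distribution) when
    n_a * n_b <= 400, else the asymptotic Kolmogorov distribution with
    the effective-n correction. p-values below 1e-15 are reported as the
    bound 1e-15 with ``p_is_bound`` set.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 values")
    method = "exact" if len(a) * len(b) <= 400 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    p = float(res.pvalue)
    bound = p < P_FLOOR
    return KSResult(
        statistic=float(res.statistic),
        pvalue=max(p, P_FLOOR),
        n_a=len(a),
        n_b=len(b),
        method="exact" if method == "exact" else "asymptotic",
        p_is_bound=bound,
    )


def mean_sem(values) -> dict:
    """Mean, SD, and SEM = SD/sqrt(n); requires >= 2 values."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need >= 2 values")
    sd = float(x.std(ddof=1))
    return {"mean": float(x.mean()), "sd": sd, "sem": sd / np.sqrt(len(x)),
            "n": int(len(x))}


def quartile_box(values) -> dict:
    """Box-plot summary: quartiles by linear interpolation (type 7),
    median, and whiskers at mean +/- 1 SD; requires >= 4 values."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError("need >= 4 values for quartiles")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    m = mean_sem(x)
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "mean": m["mean"],
        "whisker_low": m["mean"] - m["sd"], "whisker_high": m["mean"] + m["sd"],
        "quartile_convention": "linear interpolation (type 7)",
        "n": int(len(x)),
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the selected simulate -> analyze chains and write outputs.

    ``config`` keys: ``seed`` (int, required), ``modules`` (subset of
    {"cosmos", "bleach", "flipflop", "trap"}; default all), and optional
    per-module parameter overrides under the module's name. Writes CSV
    tables, ``metrics.json``, and ``pipeline.log`` under ``outdir`` and
    returns the metrics dict. Deterministic given config.
    """
    from . import pipeline_stages as ps

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("kinetomech.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        seed = int(config["seed"])
        modules = config.get("modules", ["cosmos", "bleach", "flipflop", "trap"])
        log.info("python=%s numpy=%s seed=%d modules=%s",
                 platform.python_version(), np.__version__, seed, modules)
        metrics: dict = {"seed": seed}
        stage_fns = {
            "cosmos": ps.stage_cosmos,
            "bleach": ps.stage_bleach,
            "flipflop": ps.stage_flipflop,
            "trap": ps.stage_trap,
        }
        for name in modules:
            log.info("stage %s start", name)
            try:
                metrics[name] = stage_fns[name](
                    seed, config.get(name, {}), outdir, log
                )
            except Exception:
                log.exception("stage %s failed", name)
                raise
            log.info("stage %s done", name)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True, default=_json_default)
        return metrics
    finally:
        log.removeHandler(handler)
        handler.close()
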