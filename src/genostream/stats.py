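"""Correlation/regression layer over streamlining profiles.

Each indicator is regressed against genome size (Mbp) or GC content (%)
across a genome collection: Pearson r (t-test on n-2 df, primary),
Spearman rho (tie-aware) and an OLS fit.  No multiple-testing correction
is applied per panel; a Holm-adjusted column is emitted alongside for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

# (x variable, y variable) pairs of the standard indicator panel:
# 8 size-vs-architecture panels + usage/composition panels against GC.
PANEL_PAIRS: list[tuple[str, str]] = [
    ("genome_size_mbp", "gc_percent"),
    ("genome_size_mbp", "mean_igs_bp"),
    ("genome_size_mbp", "coding_density_percent"),
    ("genome_size_mbp", "mean_cds_bp"),
    ("genome_size_mbp", "overlapping_cds_percent"),
    ("genome_size_mbp", "n_paralogs"),
    ("genome_size_mbp", "n_histidine_kinases"),
    ("genome_size_mbp", "n_sigma_factors"),
    ("gc_percent", "stop_taa_percent"),
    ("gc_percent", "stop_tag_percent"),
    ("gc_percent", "lys_percent"),
    ("gc_percent", "arg_percent"),
    ("gc_percent", "c_per_aa"),
    ("gc_percent", "n_per_aa"),
    ("gc_percent", "s_per_aa"),
]


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    slope: float | None
    intercept: float | None
    slope_stderr: float | None
    significant: bool | None
    defined: bool = True

    def to_row(self) -> dict:
        return dict(self.__dict__)


def correlate(profiles, x_field: str, y_field: str, *,
              alpha: float = 0.05) -> CorrelationResult:
    """Pearson/Spearman/OLS for one indicator pair across profiles.

    Profiles may be StreamliningProfile objects or dicts; genome size is
    exposed in Mbp under ``genome_size_mbp``.  Zero variance in either
    variable yields a flagged undefined result rather than NaNs.
    """
    rows = [p.to_row() if hasattr(p, "to_row") else dict(p) for p in profiles]
    for r in rows:
        r.setdefault("genome_size_mbp", r.get("genome_size_bp", np.nan) / 1e6)
    x = np.array([r[x_field] for r in rows], dtype=float)
    y = np.array([r[y_field] for r in rows], dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >=3 profiles with {x_field} and {y_field}; got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(x_field, y_field, n, None, None, None, None,
                                 None, None, None, None, defined=False)
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    ols = sps.linregress(x, y)
    return CorrelationResult(
        x_name=x_field, y_name=y_field, n=n,
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        slope=float(ols.slope), intercept=float(ols.intercept),
        slope_stderr=float(ols.stderr),
        significant=bool(pr.pvalue < alpha),
    )


def streamlining_report(profiles, *, alpha: float = 0.05,
                        pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """One CorrelationResult row per indicator panel, plus Holm adjustment."""
    profiles = list(profiles)
    results = [correlate(profiles, x, y, alpha=alpha)
               for x, y in (pairs or PANEL_PAIRS)]
    df = pd.DataFrame([r.to_row() for r in results])
    df["pearson_p_holm"] = _holm(df["pearson_p"].to_numpy(dtype=float))
    return df


def _holm(pvals: np.ndarray) -> np.ndarray:
    out = np.full_like(pvals, np.nan, dtype=float)
    ok = ~np.isnan(pvals)
    p = pvals[ok]
    m = len(p)
    order = np.argsort(p)
    adj = np.maximum.accumulate(np.minimum((m - np.arange(m)) * p[order], 1.0))
    vals = np.empty(m)
    vals[order] = adj
    out[ok] = vals
    return out


def plot_report(profiles, path, pairs: list[tuple[str, str]] | None = None) -> None:
    """Scatter grid of the indicator panels (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [p.to_row() if hasattr(p, "to_row") else dict(p) for p in profiles]
    for r in rows:
        r.setdefault("genome_size_mbp", r.get("genome_size_bp", np.nan) / 1e6)
    pairs = pairs or PANEL_PAIRS
    ncol = 4
    nrow = int(np.ceil(len(pairs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow))
    for ax, (xf, yf) in zip(np.ravel(axes), pairs):
        ax.scatter([r[xf] for r in rows], [r[yf] for r in rows], s=12)
        ax.set_xlabel(xf)
        ax.set_ylabel(yf)
    for ax in np.ravel(axes)[len(pairs):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
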