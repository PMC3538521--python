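"""Library profiling and chemical-space analysis.

Distribution summaries per descriptor (mean, SD, histogram), pairwise library
comparison (mean differences and two-sample Kolmogorov–Smirnov statistics),
ordinary least-squares correlation, and standardized (correlation-matrix)
principal component analysis with shared-basis 2D score plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: The eight properties most commonly inspected in drug-likeness profiling.
KEY_PROPERTIES = ["AlogP", "logD7.4", "logS", "MW", "N_rot", "PSA", "N_HBD", "N_HBA"]

#: Default histogram bin widths for selected descriptors (others get 20 equal
#: bins over the observed range).
DEFAULT_BIN_WIDTHS = {"MW": 50.0, "AlogP": 0.5, "logD7.4": 0.5, "logS": 0.5,
                      "PSA": 10.0, "N_rot": 1.0, "N_HBD": 1.0, "N_HBA": 1.0}


@dataclass
class LibraryProfile:
    name: str
    n: int
    means: pd.Series
    sds: pd.Series
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # descriptor -> (edges, rel. freq)


def _numeric(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns
            if c not in ("name", "flags") and pd.api.types.is_numeric_dtype(table[c])]
    return table[cols]


def profile_library(
    table: pd.DataFrame,
    name: str = "",
    histogram_descriptors: list[str] | None = None,
    bin_widths: dict[str, float] | None = None,
) -> LibraryProfile:
    """Means, sample SDs and relative-frequency histograms over non-flagged
    (non-NaN) values; histograms default to the eight key properties."""
    if table.empty:
        raise ValueError("empty descriptor table")
    num = _numeric(table)
    if histogram_descriptors is None:
        histogram_descriptors = [c for c in KEY_PROPERTIES if c in num.columns]
    widths = dict(DEFAULT_BIN_WIDTHS)
    if bin_widths:
        widths.update(bin_widths)

    histograms = {}
    for col in histogram_descriptors:
        vals = num[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        lo, hi = vals.min(), vals.max()
        if col in widths and hi > lo:
            bw = widths[col]
            edges = np.arange(np.floor(lo / bw) * bw, np.ceil(hi / bw) * bw + bw, bw)
        elif hi > lo:
            edges = np.linspace(lo, hi, 21)
        else:
            edges = np.array([lo - 0.5, lo + 0.5])
        counts, edges = np.histogram(vals, bins=edges)
        histograms[col] = (edges, counts / vals.size)

    return LibraryProfile(
        name=name,
        n=len(table),
        means=num.mean(),
        sds=num.std(ddof=1).fillna(0.0),
        histograms=histograms,
    )


def compare_libraries(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise mean differences and two-sample KS statistics per descriptor.

    ``tables`` maps library name to its descriptor table; all tables must
    share descriptor columns.  Rows: (library_a, library_b, descriptor,
    mean_diff = mean_a - mean_b, ks).
    """
    if len(tables) < 2:
        raise ValueError("need at least two libraries")
    names = list(tables)
    cols = set(_numeric(tables[names[0]]).columns)
    for nm in names[1:]:
        if set(_numeric(tables[nm]).columns) != cols:
            raise ValueError("descriptor-name mismatch between libraries")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = _numeric(tables[a]), _numeric(tables[b])
            for col in na.columns:
                va = na[col].dropna().to_numpy(dtype=float)
                vb = nb[col].dropna().to_numpy(dtype=float)
                if va.size == 0 or vb.size == 0:
                    continue
                if np.array_equal(va, vb):
                    ks = 0.0
                else:
                    ks = float(stats.ks_2samp(va, vb).statistic)
                rows.append({"library_a": a, "library_b": b, "descriptor": col,
                             "mean_diff": float(va.mean() - vb.mean()), "ks": ks})
    return pd.DataFrame(rows)


def correlate(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Ordinary least squares y = slope*x + intercept plus Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length arrays with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue)}


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # descriptor x component
    scores: np.ndarray              # molecule x component
    explained: np.ndarray           # variance fractions, non-increasing
    columns: list[str] = field(default_factory=list)
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def project(self, table: pd.DataFrame) -> np.ndarray:
        """Project another descriptor table onto this (pooled) basis."""
        z = _standardize_with(table[self.columns], self.means, self.sds)
        return z @ self.loadings.to_numpy()


def _standardize_with(table: pd.DataFrame, means, sds) -> np.ndarray:
    x = table.to_numpy(dtype=float)
    # flagged-undefined values are imputed with the (fit-time) column mean,
    # which maps to 0 after standardization
    idx = np.where(np.isnan(x))
    x[idx] = np.take(means, idx[1])
    return (x - means) / sds


def run_pca(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA on the correlation matrix of standardized descriptor columns.

    Constant columns are dropped (they carry no variance and cannot be
    standardized); NaN cells are imputed with the column mean.  The sign of
    each loading vector is fixed so its largest-magnitude entry is positive,
    making results deterministic.  Explained fractions are eigenvalues over
    the total variance of all retained columns.
    """
    num = _numeric(table)
    keep = [c for c in num.columns if num[c].nunique(dropna=True) > 1]
    if len(keep) < n_components:
        raise ValueError(
            f"only {len(keep)} non-constant columns for {n_components} components")
    num = num[keep]
    means = num.mean().to_numpy()
    sds = num.std(ddof=1).to_numpy()
    z = _standardize_with(num, means, sds)
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1][:n_components]
    eigvals_sel = eigvals[order]
    vecs = eigvecs[:, order]
    for k in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    loadings = pd.DataFrame(vecs, index=keep,
                            columns=[f"PC{k + 1}" for k in range(len(order))])
    scores = z @ vecs
    explained = np.clip(eigvals_sel, 0, None) / len(keep)
    return PCAResult(loadings=loadings, scores=scores, explained=explained,
                     columns=keep, means=means, sds=sds)


def plot_scores(
    pooled: PCAResult,
    tables: dict[str, pd.DataFrame],
    out_dir,
    prefix: str = "pca",
):
    """One score-plot panel per library in a common (pooled-fit) basis with
    shared axis limits. Returns the written file path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    projections = {nm: pooled.project(t) if len(t) else np.empty((0, 2))
                   for nm, t in tables.items()}
    allpts = np.vstack([p for p in projections.values() if p.size] or [np.zeros((1, 2))])
    pad = 0.05 * max(np.ptp(allpts[:, 0]), np.ptp(allpts[:, 1]), 1.0)
    xlim = (allpts[:, 0].min() - pad, allpts[:, 0].max() + pad)
    ylim = (allpts[:, 1].min() - pad, allpts[:, 1].max() + pad)

    fig, axes = plt.subplots(1, len(projections), figsize=(4 * len(projections), 4),
                             squeeze=False)
    for ax, (nm, pts) in zip(axes[0], projections.items()):
        if pts.size:
            ax.scatter(pts[:, 0], pts[:, 1], s=3, alpha=0.4)
        ax.set_xlim(*xlim)
        ax.set_ylim(*ylim)
        ax.set_title(f"{nm} (n={len(pts)})")
        ax.set_xlabel(f"PC1 ({pooled.explained[0] * 100:.1f}%)")
        ax.set_ylabel(f"PC2 ({pooled.explained[1] * 100:.1f}%)")
    fig.tight_layout()
    path = out_dir / f"{prefix}_scores.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
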