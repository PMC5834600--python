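"""Profile-level summaries and figure-style reporting.

Rows of a :class:`ProfileMatrix`-style frame are samples (donor × condition),
columns are markers, values are %-positive on the 0–100 scale.  PCA and
hierarchical clustering summarise how the two culture conditions separate on
their surface-protein profiles; the report renderer writes the heatmaps,
histogram overlays, PCA scatter and stain-index chart alongside a plain-text
summary with deterministic content.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list, fcluster
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io import POP_POS, POP_NEG
from .screening import ScreenResult

__all__ = [
    "build_profile_matrix",
    "pca_profiles",
    "hcluster_profiles",
    "render_report",
]

logger = logging.getLogger("lyoscreen.profiles")


def build_profile_matrix(result: ScreenResult, subset: str = "all") -> pd.DataFrame:
    """Samples × markers %-positive matrix from a screen result.

    ``subset`` selects columns: ``all`` (whole panel), ``positive`` or
    ``enriched`` (flagged markers only).  Row labels are ``donor-condition``;
    missing entries are imputed with the marker's column mean so downstream
    decompositions see a complete matrix."""
    pct = result.pct_table
    wide = pct.pivot_table(index=["donor", "population"], columns="marker",
                           values="pct_positive", aggfunc="mean")
    if subset != "all":
        flag = result.classification[subset]
        keep = [m for m in wide.columns if m in flag.index and bool(flag.loc[m])]
        wide = wide[keep]
    wide = wide.fillna(wide.mean())
    wide.index = [f"{d}-{p}" for d, p in wide.index]
    return wide


def pca_profiles(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the profile matrix on column-centered, unscaled percentages.

    Returns per-sample scores and the explained-variance fractions
    (non-increasing, summing to ≤ 1).  A constant matrix yields all-zero
    scores with a warning rather than an error."""
    if len(matrix) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    n_components = min(n_components, min(x.shape))
    centered = x - x.mean(axis=0)
    if not np.any(centered):
        logger.warning("constant profile matrix: zero-variance PCA")
        scores = np.zeros((x.shape[0], n_components))
        return (pd.DataFrame(scores, index=matrix.index,
                             columns=[f"PC{i + 1}" for i in range(n_components)]),
                np.zeros(n_components))
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(centered)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), model.explained_variance_ratio_


def hcluster_profiles(matrix: pd.DataFrame, metric: str = "euclidean",
                      method: str = "average") -> dict:
    """Agglomerative clustering of samples and markers (Euclidean, average
    linkage by default).

    Returns the sample and marker linkage matrices, the leaf orderings, and
    the top split of the samples (two-cluster cut)."""
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    sample_link = linkage(pdist(x, metric=metric), method=method)
    sample_order = [matrix.index[i] for i in leaves_list(sample_link)]
    if x.shape[1] >= 2:
        marker_link = linkage(pdist(x.T, metric=metric), method=method)
        marker_order = [matrix.columns[i] for i in leaves_list(marker_link)]
    else:
        marker_link = None
        marker_order = list(matrix.columns)
    cut = fcluster(sample_link, t=2, criterion="maxclust")
    top_split = {label: sorted(matrix.index[cut == label]) for label in np.unique(cut)}
    return {
        "sample_linkage": sample_link,
        "marker_linkage": marker_link,
        "sample_order": sample_order,
        "marker_order": marker_order,
        "top_split": top_split,
    }


def _arcsinh(x: np.ndarray, cofactor: float = 150.0) -> np.ndarray:
    return np.arcsinh(np.asarray(x, float) / cofactor)


def render_report(result: ScreenResult, out_dir: str | Path,
                  histogram_events: dict | None = None,
                  arcsinh_cofactor: float = 150.0) -> dict[str, Path]:
    """Write figure-style outputs and a deterministic text summary.

    Produces a %-positive heatmap ordered by the clustering, a PCA scatter,
    a stain-index bar chart for enriched markers, one reporter-histogram
    overlay per enriched marker when per-marker event samples are supplied
    (``histogram_events``: marker → {population: reporter array}; the display
    transform is arcsinh, statistics stay linear), and ``summary.txt`` with
    the flag counts.  File names are deterministic; rendering the same result
    twice writes byte-identical summary text."""
    import matplotlib
    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    counts = result.flag_counts()
    enriched = result.enriched_markers()

    # heatmap of positive markers (fall back to the full panel when none)
    subset = "positive" if counts["positive"] else "all"
    matrix = build_profile_matrix(result, subset=subset)
    if len(matrix) >= 2 and matrix.shape[1] >= 1:
        clus = hcluster_profiles(matrix) if matrix.shape[1] >= 2 else None
        ordered = matrix.loc[clus["sample_order"], clus["marker_order"]] if clus else matrix
        fig, ax = plt.subplots(figsize=(10, 3 + 0.2 * len(ordered)))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=100)
        ax.set_yticks(range(len(ordered)), ordered.index)
        ax.set_xlabel(f"{ordered.shape[1]} markers ({subset})")
        fig.colorbar(im, ax=ax, label="% positive")
        path = out / "heatmap_pct_positive.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["heatmap"] = path

        if len(matrix) >= 2:
            scores, evr = pca_profiles(matrix)
            fig, ax = plt.subplots(figsize=(5, 4))
            for cond, color in ((POP_POS, "tab:blue"), (POP_NEG, "tab:red")):
                rows = [i for i in scores.index if i.endswith(f"-{cond}")]
                sub = scores.loc[rows]
                ax.scatter(sub["PC1"], sub.get("PC2", 0 * sub["PC1"]), label=cond, color=color)
            ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
            if len(evr) > 1:
                ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
            ax.legend()
            path = out / "pca_profiles.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written["pca"] = path

    if enriched:
        cls = result.classification.loc[enriched]
        fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(enriched)), 4))
        xpos = np.arange(len(enriched))
        ax.bar(xpos - 0.2, cls["si_plt"], width=0.4, label=POP_POS, color="tab:blue")
        ax.bar(xpos + 0.2, cls["si_fcs"], width=0.4, label=POP_NEG, color="tab:red")
        ax.set_xticks(xpos, enriched, rotation=90)
        ax.set_ylabel("stain index")
        ax.legend()
        fig.tight_layout()
        path = out / "stain_index_enriched.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["stain_index"] = path

    if histogram_events:
        for marker in enriched:
            pops = histogram_events.get(marker)
            if not pops:
                continue
            fig, ax = plt.subplots(figsize=(5, 3))
            for cond, color in ((POP_POS, "tab:blue"), (POP_NEG, "tab:red")):
                if cond in pops:
                    ax.hist(_arcsinh(pops[cond], arcsinh_cofactor), bins=100,
                            histtype="step", density=True, label=cond, color=color)
            ax.set_xlabel("reporter (arcsinh display)")
            ax.set_title(marker)
            ax.legend()
            fig.tight_layout()
            path = out / f"hist_{marker.replace('/', '_')}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"hist_{marker}"] = path

    lines = [
        "screen summary",
        f"markers analysed: {counts['markers']}",
        f"positive (>= threshold in one or both populations): {counts['positive']}",
        f"variable expression: {counts['variable']}",
        f"enriched (fold and p-value filter): {counts['enriched']}",
    ]
    if enriched:
        lines.append("enriched markers: " + ", ".join(enriched))
    bg = result.background
    if "ratio_fcs_over_plt" in bg.columns and len(bg):
        lines.append(f"background MFI ratio FCS/PLT: {bg['ratio_fcs_over_plt'].iloc[0]:.3f}")
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written["summary"] = summary
    return written
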