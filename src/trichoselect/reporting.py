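"""Association reporting: survival scores, trichome regressions, clustering.

Secondary analytics around the selection pipeline: relative survival scores
(highest accession set to 100%), trichome-density aggregation with
insect-specific surface rules (whiteflies roam both leaf surfaces, thrips
larvae are confined to the adaxial side), ordinary least-squares fits of
survival on density, complete-linkage clustering of metabolites by their
abundance profile across accessions, and machine-readable report files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "RegressionSummary",
    "relative_survival",
    "aggregate_density",
    "linear_fit",
    "cluster_features",
    "log_abundance_panel",
    "render_reports",
]


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def relative_survival(scores: pd.Series) -> pd.Series:
    """Percent of the highest per-accession survival score (max -> 100%)."""
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("no scores")
    if (s < 0).any():
        raise ValueError("survival scores must be >= 0")
    m = s.max()
    if m <= 0:
        raise ValueError("all survival scores are zero; relative score undefined")
    return s / m * 100.0


def aggregate_density(records: pd.DataFrame, insect: str) -> pd.DataFrame:
    """Accession x trichome-type mean density under the insect's surface rule.

    Aggregation: leaf discs -> plant x surface mean -> surface rule
    (whitefly: mean of abaxial and adaxial; thrips: adaxial only) -> mean over
    plants.
    """
    if insect not in ("whitefly", "thrips"):
        raise ValueError("insect must be 'whitefly' or 'thrips'")
    need = {"accession", "plant_id", "surface", "trichome_type", "density"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"density records missing columns {sorted(missing)}")
    if (records["density"] < 0).any():
        raise ValueError("densities must be >= 0")

    surf = (
        records.groupby(["accession", "plant_id", "surface", "trichome_type"])["density"]
        .mean()
        .reset_index()
    )
    if insect == "whitefly":
        present = surf.groupby("accession")["surface"].agg(lambda s: set(s))
        bad = present.index[present.map(lambda s: not {"abaxial", "adaxial"} <= s)]
        if len(bad):
            raise ValueError(
                f"whitefly mode needs both leaf surfaces; missing for {list(bad)}"
            )
        plant = (
            surf.groupby(["accession", "plant_id", "trichome_type"])["density"]
            .mean()  # mean of the two surfaces
            .reset_index()
        )
    else:
        plant = surf[surf["surface"] == "adaxial"].drop(columns="surface")
    out = (
        plant.groupby(["accession", "trichome_type"])["density"]
        .mean()
        .unstack("trichome_type")
    )
    return out


def linear_fit(x, y) -> RegressionSummary:
    """Ordinary least squares of y on x with r^2 and the slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    res = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(min(res.rvalue**2, 1.0)),
        p_value=float(res.pvalue),
        n=len(x),
    )


def cluster_features(
    accession_means: pd.DataFrame,
    *,
    transform: str = "log10p1",
    metric: str = "euclidean",
):
    """Complete-linkage clustering of features by their accession profile.

    ``accession_means`` is accessions x features; features are clustered on
    their column vectors, by default Euclidean distance of log10(x+1)
    abundances (taming the orders-of-magnitude spread of trichome
    metabolites), with ``transform="raw"`` and ``metric="correlation"``
    selectable.  Features are pre-sorted by id so equal-distance merges break
    ties deterministically.  Returns ``(ordered_feature_ids, linkage_matrix)``.
    """
    if accession_means.shape[1] < 2:
        raise ValueError("need at least two features to cluster")
    M = accession_means.sort_index(axis=1)
    V = M.to_numpy(dtype=float).T  # features x accessions
    if transform == "log10p1":
        V = np.log10(V + 1.0)
    elif transform != "raw":
        raise ValueError("transform must be 'log10p1' or 'raw'")
    D = pdist(V, metric=metric)
    Z = linkage(D, method="complete")
    order = leaves_list(Z)
    return [M.columns[i] for i in order], Z


def log_abundance_panel(table, feature_ids=None) -> pd.DataFrame:
    """Per accession x feature log10 mean abundance with delta-method SE.

    Mirrors bar-plot panels of selected metabolites: the plotted height is
    log10 of the replicate mean and its SE is SE(mean) / (mean * ln 10)
    (first-order propagation); both NaN where the mean is zero.
    """
    df = table.data
    if feature_ids is not None:
        df = df[df["feature_id"].isin(list(feature_ids))]
    g = df.groupby(["accession", "feature_id"])["abundance"]
    mean = g.mean()
    se = g.sem(ddof=1)
    out = pd.DataFrame({"mean": mean, "se": se}).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log10_mean"] = np.where(out["mean"] > 0, np.log10(out["mean"]), np.nan)
        out["log10_se"] = np.where(
            out["mean"] > 0, out["se"] / (out["mean"] * np.log(10)), np.nan
        )
    return out


def render_reports(
    out_dir: str | Path,
    *,
    selection=None,
    feature_table=None,
    labels: pd.DataFrame | None = None,
    survival_scores: pd.Series | None = None,
    make_plots: bool = False,
) -> dict:
    """Write machine-readable TSV/JSON reports (plots optional).

    Returns a manifest of the files written.  With an empty selection the
    summary states "no significant features" and reporting still succeeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    summary: dict = {}
    if selection is not None:
        sel_path = out / "selection.tsv"
        selection.table.to_csv(sel_path, sep="\t", index_label="feature")
        written["selection"] = str(sel_path)
        hits = selection.table.index[selection.table["selected"]].tolist()
        summary["accuracy"] = selection.accuracy
        summary["n_selected"] = len(hits)
        summary["selected_features"] = hits
        summary["message"] = (
            "no significant features" if not hits else f"{len(hits)} significant features"
        )
        if feature_table is not None and hits:
            panel = log_abundance_panel(feature_table, hits)
            panel_path = out / "abundance_panels.tsv"
            panel.to_csv(panel_path, sep="\t", index=False)
            written["abundance_panels"] = str(panel_path)

    if feature_table is not None and feature_table.accession_means().shape[1] >= 2:
        order, Z = cluster_features(feature_table.accession_means())
        heat = feature_table.accession_means().loc[:, order]
        heat_path = out / "heatmap_data.tsv"
        np.log10(heat + 1.0).to_csv(heat_path, sep="\t")
        written["heatmap_data"] = str(heat_path)

    if labels is not None:
        lab_path = out / "labels.tsv"
        labels.to_csv(lab_path, sep="\t", index=False)
        written["labels"] = str(lab_path)

    if survival_scores is not None:
        rel = relative_survival(survival_scores)
        rel_path = out / "relative_survival.tsv"
        rel.rename("relative_survival_pct").to_csv(rel_path, sep="\t")
        written["relative_survival"] = str(rel_path)

    if make_plots and selection is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        t = selection.table.sort_values("mean_importance", ascending=False).head(20)
        ax.barh(range(len(t)), t["mean_importance"], xerr=t["sd"].fillna(0))
        ax.set_yticks(range(len(t)), t.index)
        ax.invert_yaxis()
        ax.set_xlabel("mean feature importance")
        fig.tight_layout()
        plot_path = out / "importance.png"
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
        written["importance_plot"] = str(plot_path)

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str))
    written["summary"] = str(summary_path)
    return written
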