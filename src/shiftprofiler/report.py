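"""Report assembly: global per-peak summary and experiment profile matrix.

All outputs are deterministic TSVs at fixed precision (masses 4 dp, rates
and similarity 2 dp, RT shifts 1 dp): identical inputs and seed give
byte-identical files.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import PeakAnnotation
from .errors import InputError
from .localization import LocalizationProfile
from .peaks import PeakSet
from .similarity import ComparisonProfile


def _fmt(value: float | int | str, nd: int) -> str:
    if isinstance(value, str):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.{nd}f}"


def build_global_profile(
    peakset: PeakSet,
    annotations: list[PeakAnnotation],
    localization: list[LocalizationProfile],
    comparison: list[ComparisonProfile],
    quantification: pd.DataFrame,
) -> pd.DataFrame:
    """One row per retained peak, ordered by pooled PSM count descending.

    Joins on peak identity; sub-profiles that are missing for a peak render
    as empty cells (NaN), never fabricated zeros.
    """
    ann_by_peak = {a.peak_index: a for a in annotations}
    if len(ann_by_peak) != len(annotations):
        raise InputError("duplicate peak identity in annotations")
    loc_pooled = {
        p.peak_index: p for p in localization if p.experiment == "(all)"
    }
    cmp_pooled = {
        p.peak_index: p for p in comparison if p.experiment == "(all)"
    }
    experiments = [
        e for e in quantification["experiment"].unique() if e != "(all)"
    ]

    quant = quantification.set_index(["peak", "experiment"])
    rows = []
    for k, peak in enumerate(peakset.peaks):
        row: dict[str, object] = {
            "peak": k,
            "mass_shift": peak.reported_mass,
            "apex_mass": peak.apex_mass,
            "prominence": peak.prominence,
            "snr": peak.snr,
            "left_bound": peak.left_bound,
            "right_bound": peak.right_bound,
            "psms": int(quant.loc[(k, "(all)"), "count"]),
        }
        ann = ann_by_peak.get(k)
        row["annotation"] = ann.annotation if ann else float("nan")
        row["annotation_residual"] = ann.residual_error if ann else float("nan")

        cp = cmp_pooled.get(k)
        if cp is not None and cp.n_compared > 0:
            row["pct_in_unmodified"] = 100.0 * cp.fraction_with_counterpart
            row["similarity"] = cp.mean_similarity
            row["delta_rt"] = cp.mean_delta_rt
        else:
            row["pct_in_unmodified"] = float("nan")
            row["similarity"] = float("nan")
            row["delta_rt"] = float("nan")

        lp = loc_pooled.get(k)
        if lp is not None and lp.n_localizable > 0:
            row["localized_fraction"] = lp.localized_fraction
            row["nterm_rate_pct"] = 100.0 * lp.nterm_rate
            top = lp.top_residues(2)
            row["AA_1"] = f"{top[0][0]} ({top[0][1]:.1f})" if len(top) > 0 else ""
            row["AA_2"] = f"{top[1][0]} ({top[1][1]:.1f})" if len(top) > 1 else ""
        else:
            row["localized_fraction"] = float("nan")
            row["nterm_rate_pct"] = float("nan")
            row["AA_1"] = ""
            row["AA_2"] = ""

        for label in experiments:
            row[f"count[{label}]"] = int(quant.loc[(k, label), "count"])
            row[f"normalized[{label}]"] = float(quant.loc[(k, label), "normalized"])
        rows.append(row)

    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["psms", "mass_shift"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def build_experiment_matrix(
    quantification: pd.DataFrame, zscore: bool = False
) -> pd.DataFrame:
    """Experiments x peaks matrix of normalized spectral counts.

    With ``zscore``, each column is standardized with the sample (n-1)
    standard deviation; constant columns map to all zeros.
    """
    quant = quantification[quantification["experiment"] != "(all)"]
    if quant.empty:
        return pd.DataFrame()
    mat = quant.pivot(index="experiment", columns="peak", values="normalized")
    mass_by_peak = dict(
        zip(quantification["peak"], quantification["reported_mass"])
    )
    mat.columns = [f"{mass_by_peak[k]:.4f}" for k in mat.columns]
    if zscore:
        values = mat.to_numpy(dtype=float)
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(
            values.shape[1]
        )
        out = np.zeros_like(values)
        nz = sd > 0
        out[:, nz] = (values[:, nz] - mean[nz]) / sd[nz]
        mat = pd.DataFrame(out, index=mat.index, columns=mat.columns)
    return mat


# column -> decimal places for the fixed-precision TSV renderers
_GLOBAL_PRECISION = {
    "mass_shift": 4,
    "apex_mass": 4,
    "prominence": 2,
    "snr": 4,
    "left_bound": 4,
    "right_bound": 4,
    "annotation_residual": 4,
    "pct_in_unmodified": 2,
    "similarity": 2,
    "delta_rt": 1,
    "localized_fraction": 2,
    "nterm_rate_pct": 2,
}


def _write_df(df: pd.DataFrame, path: Path, precision: dict[str, int]) -> None:
    out = df.copy()
    for col, nd in precision.items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: _fmt(v, nd))
    for col in out.columns:
        if col.startswith("normalized"):
            out[col] = out[col].map(lambda v: _fmt(v, 4))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_reports(
    directory: str | os.PathLike,
    peakset: PeakSet,
    annotations: list[PeakAnnotation],
    localization: list[LocalizationProfile],
    comparison: list[ComparisonProfile],
    quantification: pd.DataFrame,
) -> dict[str, Path]:
    """Write the five deterministic TSV reports; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    global_df = build_global_profile(
        peakset, annotations, localization, comparison, quantification
    )
    paths["global"] = directory / "global.profile.tsv"
    _write_df(global_df, paths["global"], _GLOBAL_PRECISION)

    peaks_df = pd.DataFrame(
        [
            {
                "peak": k,
                "reported_mass": p.reported_mass,
                "apex_mass": p.apex_mass,
                "prominence": p.prominence,
                "snr": p.snr,
                "left_bound": p.left_bound,
                "right_bound": p.right_bound,
                "psms": p.n_assigned,
            }
            for k, p in enumerate(peakset.peaks)
        ],
        columns=[
            "peak", "reported_mass", "apex_mass", "prominence", "snr",
            "left_bound", "right_bound", "psms",
        ],
    )
    paths["peaks"] = directory / "peaks.tsv"
    _write_df(
        peaks_df,
        paths["peaks"],
        {
            "reported_mass": 4, "apex_mass": 4, "prominence": 2,
            "snr": 4, "left_bound": 4, "right_bound": 4,
        },
    )

    loc_df = pd.DataFrame(
        [
            {
                "peak": p.peak_index,
                "experiment": p.experiment,
                "localized_fraction": p.localized_fraction if p.n_attempted else float("nan"),
                "nterm_rate_pct": 100.0 * p.nterm_rate if p.n_localizable else float("nan"),
                "AA_1": f"{t[0][0]} ({t[0][1]:.1f})" if len(t := p.top_residues(2)) > 0 else "",
                "AA_2": f"{t[1][0]} ({t[1][1]:.1f})" if len(t) > 1 else "",
            }
            for p in localization
        ],
        columns=["peak", "experiment", "localized_fraction", "nterm_rate_pct", "AA_1", "AA_2"],
    )
    paths["localization"] = directory / "localization.tsv"
    _write_df(loc_df, paths["localization"], {"localized_fraction": 2, "nterm_rate_pct": 2})

    sim_df = pd.DataFrame(
        [
            {
                "peak": p.peak_index,
                "experiment": p.experiment,
                "mean_similarity": p.mean_similarity,
                "mean_delta_rt": p.mean_delta_rt,
                "n_compared": p.n_compared,
                "pct_in_unmodified": 100.0 * p.fraction_with_counterpart
                if p.n_assigned
                else float("nan"),
            }
            for p in comparison
        ],
        columns=[
            "peak", "experiment", "mean_similarity", "mean_delta_rt",
            "n_compared", "pct_in_unmodified",
        ],
    )
    paths["similarity"] = directory / "similarity.tsv"
    _write_df(
        sim_df,
        paths["similarity"],
        {"mean_similarity": 2, "mean_delta_rt": 1, "pct_in_unmodified": 2},
    )

    matrix = build_experiment_matrix(quantification, zscore=True)
    paths["matrix"] = directory / "experiment.matrix.tsv"
    out = matrix.copy()
    for col in out.columns:
        out[col] = out[col].map(lambda v: _fmt(v, 4))
    out.to_csv(paths["matrix"], sep="\t", index=True, lineterminator="\n")
    return paths
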