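"""Differential metabolomics statistics feeding the footprint scorer.

Pipeline, mirroring standard LC-MS practice: drop metabolites with >= 30%
relative standard deviation across pooled-QC injections, normalise each
sample's peak areas to its total ion count, log2-transform with a
half-minimum pseudo-count, regress out additive batch effects with a linear
model, then compute empirical-Bayes moderated two-group t-statistics with
Benjamini-Hochberg adjusted p-values.

The moderated t shrinks per-metabolite variances toward a common prior:
s_tilde^2 = (d0*s0^2 + d*s^2)/(d0 + d), with hyperparameters (d0, s0^2)
fitted by moments on log s^2 using digamma/trigamma closed forms;
t = dmean/(s_tilde*sqrt(1/n1 + 1/n2)) on d0 + d degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .errors import ContrastError, DesignError, FormatError

__all__ = [
    "AbundanceMatrix",
    "qc_rsd_filter",
    "tic_normalize",
    "log2_transform",
    "remove_batch_effect",
    "moderated_t",
    "bh_adjust",
    "differential_pipeline",
]

DESIGN_COLUMNS = ["sample", "group", "batch", "is_qc"]


@dataclass
class AbundanceMatrix:
    """Samples x metabolites peak areas plus per-sample annotations.

    ``areas`` is indexed by sample name; ``design`` is indexed identically
    with columns group, batch (strings) and is_qc (bool).  QC samples are
    pooled-sample injections used only for reproducibility filtering; their
    group label may be empty.  ``log_scale`` marks matrices that have been
    log2-transformed (negative values are then legitimate).
    """

    areas: pd.DataFrame
    design: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.design.index):
            raise FormatError("areas and design sample indices differ")
        if not self.log_scale and (self.areas.values < 0).any():
            raise FormatError("negative peak areas")
        non_qc = self.design.loc[~self.design["is_qc"].astype(bool)]
        if (non_qc["group"].astype(str) == "").any() or non_qc["group"].isna().any():
            raise FormatError("non-QC sample with empty group label")
        if (non_qc["batch"].astype(str) == "").any() or non_qc["batch"].isna().any():
            raise FormatError("non-QC sample with empty batch label")

    @property
    def qc_mask(self) -> pd.Series:
        return self.design["is_qc"].astype(bool)

    def drop_qc(self) -> "AbundanceMatrix":
        keep = ~self.qc_mask
        return AbundanceMatrix(
            self.areas.loc[keep].copy(), self.design.loc[keep].copy(), self.log_scale
        )

    @classmethod
    def from_csv(cls, areas_path: str | Path, design_path: str | Path) -> "AbundanceMatrix":
        areas = pd.read_csv(areas_path, index_col=0)
        design = pd.read_csv(design_path, dtype={"group": str, "batch": str})
        for col in DESIGN_COLUMNS:
            if col not in design.columns:
                raise FormatError(f"design table: missing column {col!r}")
        design = design.set_index("sample")
        design["is_qc"] = design["is_qc"].astype(bool)
        design = design.reindex(areas.index)
        if design[["is_qc"]].isna().any().any():
            raise FormatError("design table does not cover all samples")
        design[["group", "batch"]] = design[["group", "batch"]].fillna("")
        return cls(areas, design)

    def to_csv(self, areas_path: str | Path, design_path: str | Path) -> None:
        self.areas.sort_index().to_csv(areas_path, float_format="%.12g")
        out = self.design.sort_index().reset_index()
        out.columns = DESIGN_COLUMNS
        out.to_csv(design_path, index=False)


def qc_rsd_filter(
    matrix: AbundanceMatrix, threshold: float = 0.30
) -> tuple[AbundanceMatrix, list[str]]:
    """Drop metabolites with QC relative standard deviation >= threshold.

    RSD is sd/mean over the QC injections (population sd would change no
    decision at these thresholds; sample sd, ddof=1, is used).  Requires at
    least two QC samples.
    """
    qc = matrix.areas.loc[matrix.qc_mask]
    if len(qc) < 2:
        raise DesignError(f"QC RSD filter needs >= 2 QC samples, found {len(qc)}")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    rsd = rsd.fillna(np.inf)  # zero-mean QC signal is unquantifiable
    dropped = sorted(rsd.index[rsd >= threshold])
    kept = matrix.areas.drop(columns=dropped)
    return AbundanceMatrix(kept, matrix.design.copy(), matrix.log_scale), dropped


def tic_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample's areas by its total ion count (row total).

    Normalised rows sum to 1; an all-zero sample raises naming the sample.
    """
    if matrix.log_scale:
        raise DesignError("TIC normalisation applies to raw areas, not log-scale data")
    totals = matrix.areas.sum(axis=1)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise DesignError(f"sample(s) with zero total ion count: {list(zero)}")
    return AbundanceMatrix(matrix.areas.div(totals, axis=0), matrix.design.copy())


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 with a half-minimum pseudo-count (half the smallest positive area)."""
    values = matrix.areas.values
    positive = values[values > 0]
    if positive.size == 0:
        raise DesignError("cannot log-transform an all-zero matrix")
    pseudo = positive.min() / 2.0
    return AbundanceMatrix(np.log2(matrix.areas + pseudo), matrix.design.copy(),
                           log_scale=True)


def _indicator(labels: pd.Series, drop_first: bool = False) -> np.ndarray:
    levels = sorted(labels.unique())
    if drop_first:
        levels = levels[1:]
    return np.column_stack([(labels == lv).to_numpy(float) for lv in levels]) if levels \
        else np.empty((len(labels), 0))


def remove_batch_effect(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Regress out additive batch effects on log-scale data.

    Per metabolite, fits least squares on group + batch indicator columns and
    subtracts the fitted batch terms, keeping group effects intact (the same
    linear-model correction limma's removeBatchEffect performs).  QC samples
    participate as their own pseudo-group.  A single batch is an identity
    transform (with a warning); a batch structure perfectly confounded with
    groups raises :class:`DesignError`.
    """
    design = matrix.design
    groups = design["group"].astype(str).where(~matrix.qc_mask, "__QC__")
    batches = design["batch"].astype(str).where(
        (design["batch"].astype(str) != "") & ~design["batch"].isna(), "__none__"
    )
    if batches.nunique() < 2:
        warnings.warn("single batch: batch correction is an identity transform")
        return AbundanceMatrix(matrix.areas.copy(), matrix.design.copy(), matrix.log_scale)
    xg = _indicator(groups)
    xb = _indicator(batches, drop_first=True)
    x = np.hstack([xg, xb])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("batch is confounded with group: cannot separate effects")
    y = matrix.areas.to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    batch_fit = xb @ beta[xg.shape[1]:, :]
    corrected = pd.DataFrame(
        y - batch_fit, index=matrix.areas.index, columns=matrix.areas.columns
    )
    return AbundanceMatrix(corrected, matrix.design.copy(), matrix.log_scale)


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square prior (d0, s0^2).

    Works on z = log s^2: E z = log s0^2 + digamma(d/2) - log(d/2) +
    digamma(d0/2)... rearranged so the excess variance of z over
    trigamma(df/2) identifies d0 via the trigamma inverse.  Returns
    (inf, exp(mean)) when the excess is non-positive (variances already
    consistent with a single common value) and (0, median s^2) when fewer
    than 3 finite variances prevent the fit.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if e.size < 3:
        warnings.warn("too few metabolites to fit the variance prior; using d0=0")
        return 0.0, float(np.median(s2))
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(evar))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _moderated_t_arrays(
    y1: np.ndarray, y2: np.ndarray, d0: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Core moderated-t computation on two (samples x metabolites) arrays.

    Returns (t, p, log2fc, d0, s0_sq).  ``d0`` may be forced (0 recovers the
    classical pooled t) or fitted from the data when None.
    """
    n1, n2 = y1.shape[0], y2.shape[0]
    df = n1 + n2 - 2
    mean1, mean2 = y1.mean(axis=0), y2.mean(axis=0)
    ss = ((y1 - mean1) ** 2).sum(axis=0) + ((y2 - mean2) ** 2).sum(axis=0)
    s2 = ss / df
    if d0 is None:
        d0, s0_sq = _fit_f_dist(s2, df)
    else:
        s0_sq = float(np.median(np.maximum(s2, 1e-300)))
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    delta = mean1 - mean2
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    return t, p, delta, d0, s0_sq


def moderated_t(
    matrix: AbundanceMatrix,
    contrast: tuple[str, str],
    d0: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per metabolite.

    ``contrast`` is (numerator_group, denominator_group); positive t means
    higher in the numerator group.  Input must already be on log2 scale.
    Returns a DataFrame (metabolite, t_value, log2fc, p, adj_p) with the
    fitted hyperparameters in ``df.attrs['d0']`` / ``df.attrs['s0_sq']``.
    """
    g1, g2 = contrast
    design = matrix.design
    groups = design.loc[~matrix.qc_mask, "group"].astype(str)
    for g in (g1, g2):
        if g not in set(groups):
            raise ContrastError(f"group {g!r} absent from design")
    y1 = matrix.areas.loc[groups.index[groups == g1]].to_numpy(float)
    y2 = matrix.areas.loc[groups.index[groups == g2]].to_numpy(float)
    if y1.shape[0] < 2 or y2.shape[0] < 2:
        raise DesignError("both contrast groups need >= 2 samples")
    t, p, delta, d0_fit, s0_sq = _moderated_t_arrays(y1, y2, d0)
    out = pd.DataFrame(
        {
            "metabolite": matrix.areas.columns,
            "t_value": t,
            "log2fc": delta,
            "p": p,
            "adj_p": bh_adjust(p),
        }
    )
    out.attrs["d0"] = d0_fit
    out.attrs["s0_sq"] = s0_sq
    out.attrs["contrast"] = f"{g1}-{g2}"
    return out


def bh_adjust(p: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_p[i] = min over j with p[j] >= p[i] of p[j]*m/rank(j), capped at 1;
    monotone and elementwise >= p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def differential_pipeline(
    matrix: AbundanceMatrix,
    contrast: tuple[str, str],
    qc_rsd_threshold: float | None = 0.30,
) -> pd.DataFrame:
    """QC-RSD filter -> TIC normalise -> log2 -> batch regression -> moderated t.

    Set ``qc_rsd_threshold`` to None to skip the QC step (e.g. designs
    without pooled-QC injections).
    """
    if qc_rsd_threshold is not None:
        matrix, _ = qc_rsd_filter(matrix, qc_rsd_threshold)
    matrix = tic_normalize(matrix)
    matrix = log2_transform(matrix)
    matrix = remove_batch_effect(matrix)
    return moderated_t(matrix.drop_qc(), contrast)
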