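"""qPCR quantification: Ct calling, efficiency estimation, relative quantities.

The per-primer amplification efficiency E (per-cycle amplification factor,
2 for perfect doubling) is estimated a posteriori from the fluorescence
curves themselves, pooling all wells of a primer regardless of condition:
for each well the log-linear "window of linearity" of the baseline-
corrected curve is found by sliding a fixed-width cycle window and keeping
the best straight-line fit; the well's efficiency is 10**slope and the
primer's efficiency is the mean over wells whose window fit reaches the
R² quality bar.

Because late-cycle fluorescence saturates (reagent exhaustion), a raw
log-linear fit is biased low wherever the window touches the plateau.
When a curve has demonstrably plateaued we therefore linearize it first:
y / (1 - y/plateau) restores the underlying exponential for the logistic
saturation profile, after which the window fit is unbiased over a much
wider usable range.  Curves that never approach a plateau are fitted on
the raw log scale.

Relative quantities follow the single-gene-efficiency convention:
RQ = E**(Ct_calibrator - Ct) with the per-gene mean Ct across samples as
calibrator, then normalization by the geometric mean of the reference
genes (EEF1a and RPL8 by default) per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError, InvalidInputError

NO_AMPLIFICATION = float("nan")


def call_ct(cycles, fluorescence, threshold: float) -> float:
    """Fractional cycle at which corrected fluorescence first crosses threshold.

    The baseline is the mean of the first three cycles.  Returns NaN (the
    no-amplification flag) when the corrected curve never reaches the
    threshold.
    """
    c = np.asarray(cycles, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if len(c) < 10:
        raise InvalidInputError("amplification curve needs >= 10 cycles")
    if np.any(np.diff(c) <= 0):
        raise InvalidInputError("cycles must be strictly increasing")
    y = f - f[:3].mean()
    if threshold <= 0:
        raise InvalidInputError("threshold must be above baseline (positive)")
    above = np.nonzero(y >= threshold)[0]
    if len(above) == 0:
        return NO_AMPLIFICATION
    i = above[0]
    if i == 0:
        return float(c[0])
    y0, y1 = y[i - 1], y[i]
    if y0 > 0:
        # log-space interpolation: exact while growth is exponential
        frac = (math.log(threshold) - math.log(y0)) / (math.log(y1) - math.log(y0))
    else:
        frac = (threshold - y0) / (y1 - y0)
    return float(c[i - 1] + frac * (c[i] - c[i - 1]))


@dataclass
class WindowFit:
    well_id: str
    start_cycle: int
    slope: float
    r2: float
    efficiency: float


@dataclass
class PrimerEfficiency:
    primer_id: str
    efficiency: float
    n_wells_used: int
    window_fits: list[WindowFit] = field(default_factory=list)
    excluded_wells: list[str] = field(default_factory=list)


def _window_of_linearity(
    cycles: np.ndarray,
    y: np.ndarray,
    window: int,
    lo_frac: float = 0.02,
    hi_frac: float = 0.8,
    plateau_tol: float = 0.05,
) -> tuple[int, float, float] | None:
    """Best (start index, slope, R²) log-linear window of one corrected curve."""
    peak = y.max()
    if peak <= 0:
        return None
    # plateau detection: the last cycles have stopped growing
    tail = y[-3:]
    plateaued = (tail.max() - tail.min()) < plateau_tol * peak and peak > 0
    signal = np.full_like(y, np.nan)
    if plateaued:
        valid = (y > 0) & (y < peak)
        signal[valid] = y[valid] / (1.0 - y[valid] / peak)
    else:
        valid = y > 0
        signal[valid] = y[valid]
    usable = (y > lo_frac * peak) & (y < hi_frac * peak) & np.isfinite(signal)
    idx = np.nonzero(usable)[0]
    best = None
    for s in range(len(idx) - window + 1):
        win = idx[s:s + window]
        if win[-1] - win[0] != window - 1:  # must be contiguous cycles
            continue
        fit = stats.linregress(cycles[win], np.log10(signal[win]))
        r2 = fit.rvalue ** 2
        if best is None or r2 > best[2]:
            best = (int(win[0]), float(fit.slope), float(r2))
    return best


def estimate_efficiency(
    curves: pd.DataFrame,
    primer_id: str | None = None,
    window: int = 5,
    min_r2: float = 0.99,
) -> PrimerEfficiency:
    """Mean window-of-linearity efficiency over all wells of one primer.

    ``curves`` is long-format (well_id, primer_id, cycle, fluorescence).
    Wells whose best window fails ``min_r2`` are excluded and logged;
    if no well passes, an EstimationError names the primer.
    """
    df = curves
    if primer_id is not None:
        df = df[df["primer_id"] == primer_id]
    elif df["primer_id"].nunique() != 1:
        raise InvalidInputError("curves span several primers; pass primer_id")
    if df.empty:
        raise EstimationError(f"no curves for primer {primer_id!r}")
    primer = df["primer_id"].iloc[0]

    fits, excluded = [], []
    for well, grp in df.groupby("well_id", sort=True):
        grp = grp.sort_values("cycle")
        c = grp["cycle"].to_numpy(dtype=float)
        f = grp["fluorescence"].to_numpy(dtype=float)
        y = f - f[:3].mean()
        best = _window_of_linearity(c, y, window)
        if best is None or best[2] < min_r2 or best[1] <= 0:
            excluded.append(well)
            continue
        start, slope, r2 = best
        fits.append(WindowFit(well, int(c[start]), slope, r2, 10.0 ** slope))
    if not fits:
        raise EstimationError(
            f"efficiency estimation failed for primer {primer!r}: "
            f"no well reached R² >= {min_r2}"
        )
    eff = float(np.mean([w.efficiency for w in fits]))
    return PrimerEfficiency(primer, eff, len(fits), fits, excluded)


def estimate_all_efficiencies(curves: pd.DataFrame, window: int = 5,
                              min_r2: float = 0.99) -> pd.DataFrame:
    """Efficiency table (primer_id, efficiency, n_wells_used) for every primer."""
    rows = []
    for primer in sorted(curves["primer_id"].unique()):
        pe = estimate_efficiency(curves, primer, window=window, min_r2=min_r2)
        rows.append({"primer_id": pe.primer_id, "efficiency": pe.efficiency,
                     "n_wells_used": pe.n_wells_used})
    return pd.DataFrame(rows)


def relative_quantity(cts: pd.Series, efficiency: float) -> pd.Series:
    """RQ per sample: E**(Ct_calibrator - Ct), calibrator = mean Ct.

    ``cts`` is indexed by sample id.  Samples with missing Ct are skipped
    (dropped from the result).
    """
    if efficiency <= 1:
        raise InvalidInputError(f"efficiency must be > 1, got {efficiency}")
    valid = cts.dropna()
    if valid.empty:
        raise InvalidInputError("no valid Ct values")
    calibrator = float(valid.mean())
    return efficiency ** (calibrator - valid)


def relative_quantities(ct_table: pd.DataFrame, efficiencies: pd.DataFrame) -> pd.DataFrame:
    """Long-format RQ table from (gene_id, sample_id, Ct) and efficiencies."""
    eff = efficiencies.set_index("primer_id")["efficiency"]
    rows = []
    for gene, grp in ct_table.groupby("gene_id", sort=True):
        if gene not in eff.index:
            raise InvalidInputError(f"no efficiency estimate for gene {gene!r}")
        cts = grp.set_index("sample_id")["Ct"]
        rq = relative_quantity(cts, float(eff[gene]))
        for sample, value in rq.items():
            rows.append({"gene_id": gene, "sample_id": sample,
                         "rq": float(value)})
    return pd.DataFrame(rows)


def normalize_to_references(
    rq_table: pd.DataFrame,
    reference_genes: tuple[str, ...] = ("eef1a", "rpl8"),
) -> pd.DataFrame:
    """Divide each sample's RQs by the geometric mean of its reference RQs."""
    wide = rq_table.pivot(index="gene_id", columns="sample_id", values="rq")
    for ref in reference_genes:
        if ref not in wide.index:
            raise InvalidInputError(f"reference gene {ref!r} not measured")
    missing = wide.loc[list(reference_genes)].isna()
    if missing.any().any():
        sample = missing.any(axis=0).idxmax()
        gene = missing.any(axis=1).idxmax()
        raise InvalidInputError(
            f"reference gene {gene!r} missing in sample {sample!r}")
    factors = np.exp(np.log(wide.loc[list(reference_genes)]).mean(axis=0))
    normalized = wide / factors
    out = normalized.reset_index().melt(id_vars="gene_id",
                                        var_name="sample_id",
                                        value_name="normalized_rq")
    out = out.dropna(subset=["normalized_rq"]).reset_index(drop=True)
    out["normalization_factor"] = out["sample_id"].map(factors)
    return out


def fold_mo_vs_co(
    normalized: pd.DataFrame,
    replicate_of: dict[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-gene MO/Co fold with spread across independent replicates.

    ``replicate_of`` maps sample_id -> (condition, replicate index); when
    omitted, sample ids of the form ``Co_r1`` / ``MO_r1`` are parsed.
    Returns mean fold and S.E.M. (NaN when only one replicate exists).
    Genes with a missing or zero Co quantity in a replicate are flagged
    and that replicate excluded for them.
    """
    df = normalized.copy()
    if replicate_of is None:
        parts = df["sample_id"].str.rsplit("_", n=1, expand=True)
        if parts.shape[1] != 2:
            raise InvalidInputError("sample ids must look like 'Co_r1' / 'MO_r1'")
        df["condition"] = parts[0]
        df["replicate"] = parts[1]
    else:
        df["condition"] = df["sample_id"].map(lambda s: replicate_of[s][0])
        df["replicate"] = df["sample_id"].map(lambda s: replicate_of[s][1])

    rows = []
    for gene, grp in df.groupby("gene_id", sort=True):
        wide = grp.pivot(index="replicate", columns="condition",
                         values="normalized_rq")
        if "Co" not in wide.columns or "MO" not in wide.columns:
            rows.append({"gene_id": gene, "mean_fold": float("nan"),
                         "sem": float("nan"), "n_replicates": 0,
                         "flagged": True})
            continue
        ok = wide["Co"].notna() & (wide["Co"] > 0) & wide["MO"].notna()
        folds = (wide.loc[ok, "MO"] / wide.loc[ok, "Co"]).to_numpy()
        flagged = bool((~ok).any())
        if len(folds) == 0:
            rows.append({"gene_id": gene, "mean_fold": float("nan"),
                         "sem": float("nan"), "n_replicates": 0,
                         "flagged": True})
            continue
        sem = float(np.std(folds, ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else float("nan")
        rows.append({"gene_id": gene, "mean_fold": float(np.mean(folds)),
                     "sem": sem, "n_replicates": int(len(folds)),
                     "flagged": flagged})
    return pd.DataFrame(rows)
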