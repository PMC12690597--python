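"""Order-parameter statistics, free-energy profiles and scaling collapse.

The state of a polyplex suspension is summarized by n_NPs*, the number of
RNA-containing nanoparticles divided by the number of RNA chains: 1 means
every RNA sits in its own NP, 1/N_RNA means system-wide aggregation into a
single particle.  Frequent transitions between cluster-count states allow
a free-energy projection F(n_NPs*) = -k_B T ln P(n_NPs*), whose quadratic
fit locates the preferred state.  Above the isoelectric point, results
taken at different RNA concentrations collapse onto a single curve when
plotted against the excess charge ratio

    alphaN/P* = (alphaN/P - 1) c_RNA / c_ref,RNA + 1
    N/P*      = (N/P - N/P_iso) c_RNA / c_ref,RNA + N/P_iso

which measures the polycation excess beyond RNA neutralization, normalized
to a reference RNA concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrderParameterSeries",
    "FreeEnergyProfile",
    "ScalingInputs",
    "n_nps_star_series",
    "free_energy_profile",
    "np_star_transform",
    "sweep_summary",
]


@dataclass
class OrderParameterSeries:
    """Per-frame normalized NP count n_NPs* for one replicate."""

    steps: np.ndarray
    values: np.ndarray
    n_rna_chains: int
    replicate_id: int = 0
    alpha_np: float = math.nan

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.steps) != len(self.values):
            raise ValueError("steps/values length mismatch")


@dataclass
class FreeEnergyProfile:
    """Histogram free energy over n_NPs* bins with a quadratic fit."""

    bin_centers: np.ndarray
    f_values: np.ndarray               # k_B T units, min shifted to 0
    quad_coeffs: np.ndarray | None     # [a, b, c] of a x^2 + b x + c
    minimum: float                     # fitted (or modal) minimum location
    fit_window: tuple[float, float] | None = None


@dataclass(frozen=True)
class ScalingInputs:
    """Inputs of the excess-ratio transform (Eqs of the scaling collapse)."""

    c_rna: float
    c_ref_rna: float
    np_ratio: float
    alpha_np: float
    np_iso: float = 2.0   # 1/alpha at 50% protonation

    def __post_init__(self) -> None:
        if self.c_ref_rna <= 0:
            raise ValueError("reference RNA concentration must be positive")
        if self.np_iso <= 0:
            raise ValueError("isoelectric N/P must be positive")


def n_nps_star_series(np_counts_per_frame, n_rna_chains: int,
                      steps=None, replicate_id: int = 0,
                      alpha_np: float = math.nan) -> OrderParameterSeries:
    """n_NPs* per frame from per-frame NP lists (or RNA-NP counts).

    Only NPs containing at least one RNA chain are counted — free PEI
    clusters do not enter the order parameter, which therefore saturates
    at 1 in polycation excess and reaches 1/N_RNA at full aggregation.
    """
    if n_rna_chains <= 0:
        raise ValueError("n_rna_chains must be positive")
    counts = []
    for item in np_counts_per_frame:
        if np.isscalar(item):
            counts.append(int(item))
        else:  # a list of Nanoparticle objects
            counts.append(sum(1 for p in item if p.n_rna_chains > 0))
    values = np.asarray(counts, dtype=float) / n_rna_chains
    if steps is None:
        steps = np.arange(len(values))
    return OrderParameterSeries(np.asarray(steps), values, n_rna_chains,
                                replicate_id, alpha_np)


def free_energy_profile(series: OrderParameterSeries,
                        temperature: float = 1.0,
                        fit_window_kbt: float = 2.0,
                        min_transitions: int = 0) -> FreeEnergyProfile:
    """F(n_NPs*) = -k_B T ln P over bins of width 1/N_RNA, plus a fit.

    The histogram uses one bin per attainable cluster count k/N_RNA;
    empty bins carry no F value.  A parabola is fitted over the bins with
    F <= F_min + ``fit_window_kbt`` k_B T; with fewer than three such bins
    the fit is unavailable and the minimum is the modal bin.
    ``min_transitions`` optionally enforces a minimum number of observed
    state changes before the profile is considered meaningful.
    """
    n = series.n_rna_chains
    if min_transitions:
        transitions = int((np.diff(series.values) != 0).sum())
        if transitions < min_transitions:
            raise ValueError(
                f"only {transitions} transitions observed "
                f"(minimum {min_transitions})")
    ks = np.rint(series.values * n).astype(int)
    counts = np.bincount(ks, minlength=n + 1)[1:]  # k = 1..N_RNA
    centers_all = np.arange(1, n + 1) / n
    occupied = counts > 0
    p = counts[occupied] / counts.sum()
    f = -temperature * np.log(p)
    f -= f.min()
    centers = centers_all[occupied]
    window = f <= fit_window_kbt
    if window.sum() >= 3:
        coeffs = np.polyfit(centers[window], f[window], 2)
        if coeffs[0] > 0:
            minimum = float(-coeffs[1] / (2.0 * coeffs[0]))
        else:  # degenerate (flat or concave) fit: fall back to modal bin
            minimum = float(centers[np.argmin(f)])
        fit_window = (float(centers[window].min()), float(centers[window].max()))
    else:
        coeffs = None
        minimum = float(centers[np.argmin(f)])
        fit_window = None
    return FreeEnergyProfile(centers, f, coeffs, minimum, fit_window)


def np_star_transform(inp: ScalingInputs) -> tuple[float, float]:
    """Excess charge ratio alphaN/P* and excess N/P* of a formulation.

    alphaN/P = 1 is a fixed point for any concentration; at the reference
    concentration both transforms are the identity.
    """
    scale = inp.c_rna / inp.c_ref_rna
    alpha_star = (inp.alpha_np - 1.0) * scale + 1.0
    np_star = (inp.np_ratio - inp.np_iso) * scale + inp.np_iso
    return alpha_star, np_star


def sweep_summary(np_records: pd.DataFrame,
                  series: list[OrderParameterSeries],
                  weight: str = "none") -> pd.DataFrame:
    """Condition-level mean +/- std tables of R_h, kappa^2, charge, n_NPs*.

    ``np_records`` is the tidy per-NP table (columns alpha_np, replicate,
    frame, step, r_h, kappa2, charge_total, n_rna_chains, ...).  For every
    condition the second half of each replicate's frames (the equilibrated
    window) is averaged per replicate, then mean and standard deviation are
    taken across replicates.  ``weight`` selects per-NP averaging within a
    frame: "none" (every NP counts once) or "rna_chains" (weighted by the
    number of RNA chains, i.e. RNA-mass weighting).  Single-replicate
    conditions report std = 0 and are flagged.  The choice of weighting is
    recorded in ``DataFrame.attrs``.
    """
    if weight not in ("none", "rna_chains"):
        raise ValueError("weight must be 'none' or 'rna_chains'")

    def _equil(group: pd.DataFrame) -> pd.DataFrame:
        half = (group["step"].min() + group["step"].max()) / 2.0
        return group[group["step"] >= half]

    rows = []
    rec = np_records[np_records["n_rna_chains"] > 0]
    for (alpha, repl), group in rec.groupby(["alpha_np", "replicate"]):
        g = _equil(group)
        w = g["n_rna_chains"].to_numpy(float) if weight == "rna_chains" else None
        entry = {"alpha_np": alpha, "replicate": repl}
        for col in ("r_h", "kappa2", "charge_total", "zeta"):
            if col in g:
                vals = g[col].to_numpy(float)
                ok = np.isfinite(vals)
                if ok.any():
                    entry[col] = float(np.average(
                        vals[ok], weights=None if w is None else w[ok]))
                else:
                    entry[col] = math.nan
        rows.append(entry)
    per_rep = pd.DataFrame(rows)
    for s in series:
        half = (s.steps.min() + s.steps.max()) / 2.0
        sel = s.steps >= half
        per_rep.loc[(per_rep["alpha_np"] == s.alpha_np)
                    & (per_rep["replicate"] == s.replicate_id),
                    "n_nps_star"] = float(s.values[sel].mean())
    agg = per_rep.groupby("alpha_np").agg(["mean", "std", "count"])
    out_rows = []
    for alpha, row in agg.iterrows():
        entry = {"alpha_np": alpha}
        n_rep = None
        for col in per_rep.columns:
            if col in ("alpha_np", "replicate"):
                continue
            n_rep = int(row[(col, "count")])
            entry[f"{col}_mean"] = row[(col, "mean")]
            std = row[(col, "std")]
            entry[f"{col}_std"] = 0.0 if n_rep < 2 else float(std)
        entry["n_replicates"] = n_rep
        entry["single_replicate"] = bool(n_rep is not None and n_rep < 2)
        out_rows.append(entry)
    out = pd.DataFrame(out_rows).sort_values("alpha_np").reset_index(drop=True)
    out.attrs["weighting"] = weight
    return out
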