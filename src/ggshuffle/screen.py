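"""Screening analytics for shuffled-library variants.

Covers the downstream characterization pipeline: apparent melting
temperature (Tm^app) extraction from flavin thermal-shift melt curves,
ΔTm against a reference, calibration-line concentration estimation,
HRP-coupled absorbance-to-rate conversion, Michaelis–Menten fitting, ΔΔG
fold-stability candidate filtering, and structure-based enumeration of
mutable positions outside the cofactor shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .seqcore import MutationSpec


class NoTransition(ValueError):
    """Melt curve shows no detectable unfolding transition."""


class UninformativeCalibration(ValueError):
    """Calibration line has (near-)zero slope."""


@dataclass
class MeltCurve:
    """Temperature–fluorescence series from a thermal-shift experiment."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperatures.size < 10:
            raise ValueError("need at least 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "MeltCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label)


@dataclass
class TmResult:
    """Extracted apparent melting temperature."""

    tm_app: float
    method: Literal["derivative", "sigmoid"]
    diagnostics: dict = field(default_factory=dict)


def _two_state(T, tm, width, pre0, pre1, post0, post1):
    frac = 1.0 / (1.0 + np.exp((tm - T) / width))
    return (pre0 + pre1 * T) * (1 - frac) + (post0 + post1 * T) * frac


def extract_tm(
    curve: MeltCurve,
    method: str = "derivative",
    smoothing_window: int = 5,
) -> TmResult:
    """Tm^app from a melt curve.

    ``derivative``: Tm is the argmax of the Savitzky–Golay-smoothed first
    derivative, refined by quadratic interpolation between grid points.
    ``sigmoid``: least-squares fit of a two-state transition with linear
    pre/post baselines; Tm is the midpoint.

    Raises :class:`NoTransition` when the curve shows no net fluorescence
    increase with a derivative peak standing clear of the baseline noise.
    """
    T = curve.temperatures
    F = curve.fluorescence
    window = min(smoothing_window, len(F) if len(F) % 2 else len(F) - 1)
    window = max(window, 3)
    step = float(np.median(np.diff(T)))
    smooth = savgol_filter(F, window, polyorder=2)
    # the smoother's own first derivative is less noisy than differencing
    dF = savgol_filter(F, window, polyorder=2, deriv=1, delta=step)

    med = float(np.median(dF))
    mad = float(np.median(np.abs(dF - med)))
    peak = int(np.argmax(dF))
    amplitude = float(smooth.max() - smooth.min())
    scale = max(abs(smooth).max(), 1e-12)
    if dF[peak] <= 0 or amplitude < 1e-9 * scale:
        raise NoTransition("no transition detected: no net fluorescence increase")
    if mad > 0 and (dF[peak] - med) < 5 * 1.4826 * mad:
        raise NoTransition("no transition detected: derivative peak within noise")

    if method == "derivative":
        # parabola vertex over the points flanking the derivative peak
        lo, hi = max(0, peak - 4), min(len(T), peak + 5)
        tm = float(T[peak])
        if hi - lo >= 3:
            a, b, _ = np.polyfit(T[lo:hi], dF[lo:hi], 2)
            if a < 0:
                vertex = -b / (2 * a)
                if T[lo] <= vertex <= T[hi - 1]:
                    tm = float(vertex)
        diag = {"peak_derivative": float(dF[peak]), "grid_step": step}
        return TmResult(tm, "derivative", diag)

    if method == "sigmoid":
        p0 = [float(T[peak]), 1.0, float(smooth[0]), 0.0, float(smooth[-1]), 0.0]
        popt, pcov = curve_fit(_two_state, T, F, p0=p0, maxfev=20000)
        resid = F - _two_state(T, *popt)
        diag = {
            "rmsd": float(np.sqrt(np.mean(resid**2))),
            "width": float(popt[1]),
            "tm_se": float(np.sqrt(pcov[0, 0])),
        }
        tm = float(popt[0])
        if not T[0] <= tm <= T[-1]:
            raise NoTransition("no transition detected: fitted midpoint outside range")
        return TmResult(tm, "sigmoid", diag)

    raise ValueError(f"unknown method {method!r}")


def delta_tm(tm: float, reference_tm: float, grid: float = 0.5) -> float:
    """Tm difference against a reference, reported on the instrument grid."""
    if not (math.isfinite(tm) and math.isfinite(reference_tm)):
        raise ValueError("Tm values must be finite")
    return round((tm - reference_tm) / grid) * grid


@dataclass
class CalibrationResult:
    """Inverse prediction from an OLS calibration line."""

    concentration: float
    standard_error: float
    slope: float
    intercept: float
    extrapolated: bool


def concentration_from_calibration(
    calibration: Sequence[tuple[float, float]], query_signal: float
) -> CalibrationResult:
    """Concentration for a signal via an OLS line through (conc, signal).

    The standard error is propagated from the slope/intercept covariance by
    the delta method; queries outside the calibrated signal range are
    flagged as extrapolated.
    """
    if len(calibration) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([c for c, _ in calibration], dtype=float)
    y = np.array([s for _, s in calibration], dtype=float)
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    if abs(slope) < 1e-12 * max(1.0, float(np.std(y))):
        raise UninformativeCalibration("uninformative calibration: zero slope")
    conc = (query_signal - intercept) / slope
    # d(conc)/d(slope), d(conc)/d(intercept)
    g = np.array([-(query_signal - intercept) / slope**2, -1.0 / slope])
    se = float(np.sqrt(g @ cov @ g))
    extrapolated = not (min(y) <= query_signal <= max(y))
    return CalibrationResult(float(conc), se, float(slope), float(intercept), extrapolated)


def rate_from_absorbance(
    slope_per_min: float, path_cm: float = 1.0, epsilon_mm_cm: float = 26.0
) -> dict[str, float]:
    """Convert a 515-nm absorbance slope to a reaction rate.

    Default extinction coefficient 26 mM^-1 cm^-1 (HRP-coupled dye) and
    1 cm path.  Returns the rate in mM min^-1 and µM s^-1.
    """
    if slope_per_min < 0:
        raise ValueError("absorbance slope must be >= 0")
    if epsilon_mm_cm <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    rate_mm_min = slope_per_min / (epsilon_mm_cm * path_cm)
    return {"mM_per_min": rate_mm_min, "uM_per_s": rate_mm_min * 1000.0 / 60.0}


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def catalytic_efficiency(kcat: float, km: float, sig: int = 3) -> float:
    """kcat/Km to the reporting precision (3 significant figures)."""
    return _round_sig(kcat / km, sig)


@dataclass
class KineticFit:
    """Michaelis–Menten parameters with standard errors."""

    kcat: float  # s^-1
    km: float  # mM
    kcat_se: float
    km_se: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def kcat_over_km(self) -> float:
        return catalytic_efficiency(self.kcat, self.km)


def fit_michaelis_menten(
    data: Sequence[tuple[float, float]], enzyme_conc: float = 1.0
) -> KineticFit:
    """Nonlinear least-squares fit of v = kcat*E*S/(Km + S).

    Start values come from a Hanes–Woolf direct linearization (S/v vs S).
    Fits whose Km falls outside the substrate span, or that fail to
    converge, are returned flagged rather than raised.
    """
    if len(data) < 5:
        raise ValueError("need at least 5 substrate levels")
    S = np.array([s for s, _ in data], dtype=float)
    v = np.array([r for _, r in data], dtype=float)
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")

    # Hanes-Woolf: S/v = S/Vmax + Km/Vmax
    with np.errstate(divide="ignore", invalid="ignore"):
        y = S / v
    mask = np.isfinite(y)
    b1, b0 = np.polyfit(S[mask], y[mask], 1)
    vmax0 = 1.0 / b1 if b1 > 0 else float(v.max())
    km0 = b0 * vmax0 if b0 * vmax0 > 0 else float(np.median(S))

    def model(S, kcat, km):
        return kcat * enzyme_conc * S / (km + S)

    flags: list[str] = []
    try:
        popt, pcov = curve_fit(
            model, S, v, p0=[vmax0 / enzyme_conc, km0],
            bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt = np.array([vmax0 / enzyme_conc, km0])
        pcov = np.full((2, 2), np.nan)
        converged = False
        flags.append("non-convergence")
    kcat, km = float(popt[0]), float(popt[1])
    if not S.min() <= km <= S.max():
        flags.append("Km outside the substrate span")
    ses = np.sqrt(np.diag(pcov))
    return KineticFit(kcat, km, float(ses[0]), float(ses[1]), converged, flags)


# ---------------------------------------------------------------------------
# stability filtering and structural candidate enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdgRecord:
    """Predicted fold-stability change for one candidate mutation."""

    mutation: MutationSpec
    ddg_fold: tuple[float, ...]  # kJ/mol, one value per predictor

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.ddg_fold)
        if not vals or not all(math.isfinite(v) for v in vals):
            raise ValueError("ddg_fold needs at least one finite value")
        object.__setattr__(self, "ddg_fold", vals)


def ddg_filter(
    records: Iterable[DdgRecord],
    threshold: float = -5.0,
    combine_rule: str = "any",
) -> tuple[list[DdgRecord], dict]:
    """Keep candidates predicted at least as stabilizing as ``threshold``.

    A record passes when its combined ΔΔG^Fold is <= threshold (values
    *above* the threshold are discarded; the boundary is kept).
    ``combine_rule``: "any" (a single predictor at/below threshold
    suffices), "all", or "mean".
    """
    records = list(records)
    if combine_rule == "any":
        keep = [r for r in records if min(r.ddg_fold) <= threshold]
    elif combine_rule == "all":
        keep = [r for r in records if max(r.ddg_fold) <= threshold]
    elif combine_rule == "mean":
        keep = [r for r in records if sum(r.ddg_fold) / len(r.ddg_fold) <= threshold]
    else:
        raise ValueError(f"unknown combine_rule {combine_rule!r}")
    counts = {
        "input": len(records),
        "retained": len(keep),
        "discarded": len(records) - len(keep),
        "threshold_kj_mol": threshold,
        "combine_rule": combine_rule,
    }
    return keep, counts


def read_ddg_csv(path: str | Path) -> list[DdgRecord]:
    """Long-format CSV: columns mutation (e.g. I73V), predictor, value."""
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("mutation", sort=True):
        wt, pos, mut = label[0], int(label[1:-1]), label[-1]
        out.append(DdgRecord(MutationSpec(pos, wt, mut), tuple(grp["value"])))
    return out


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int  # 1-based author numbering
    aa: str
    coords: tuple[tuple[float, float, float], ...]  # heavy atoms, Å


@dataclass
class StructureModel:
    """Minimal structural model: residues + named heteroatom groups."""

    residues: list[Residue]
    het_groups: dict[str, tuple[tuple[float, float, float], ...]]

    @classmethod
    def from_pdb(cls, path: str | Path, het_names: Sequence[str] = ("FAD",)) -> "StructureModel":
        from Bio.PDB import PDBParser
        from Bio.PDB.Polypeptide import is_aa, protein_letters_3to1

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("model", str(path))
        model = next(structure.get_models())
        residues: list[Residue] = []
        hets: dict[str, list[tuple[float, float, float]]] = {}
        for chain in model:
            for res in chain:
                heavy = tuple(
                    tuple(float(c) for c in atom.coord)
                    for atom in res
                    if atom.element != "H"
                )
                if is_aa(res, standard=True):
                    residues.append(
                        Residue(
                            chain.id,
                            res.id[1],
                            protein_letters_3to1.get(res.get_resname(), "X"),
                            heavy,
                        )
                    )
                elif res.get_resname().strip() in het_names:
                    hets.setdefault(res.get_resname().strip(), []).extend(heavy)
        return cls(residues, {k: tuple(v) for k, v in hets.items()})


def enumerate_candidates(
    structure: StructureModel,
    het_name: str = "FAD",
    cutoff: float = 5.0,
    subs_per_position: int = 19,
    distance_convention: str = "min_heavy",
) -> tuple[int, list[Residue]]:
    """Count point-mutation candidates outside the cofactor shell.

    A residue is excluded iff its distance to any atom of the named het
    group is <= ``cutoff`` Å; remaining positions each contribute
    ``subs_per_position`` (19) substitutions.  Distance conventions:
    ``min_heavy`` (default, closest heavy atom), ``ca`` (Cα only — the
    first listed atom), or ``any`` (alias of min over the stored atoms).
    """
    if het_name not in structure.het_groups:
        raise KeyError(f"het group {het_name!r} not present in the structure")
    het = np.array(structure.het_groups[het_name], dtype=float)
    retained: list[Residue] = []
    for res in structure.residues:
        if distance_convention == "ca":
            pts = np.array(res.coords[:1], dtype=float)
        elif distance_convention in ("min_heavy", "any"):
            pts = np.array(res.coords, dtype=float)
        else:
            raise ValueError(f"unknown distance convention {distance_convention!r}")
        d = np.sqrt(((pts[:, None, :] - het[None, :, :]) ** 2).sum(-1)).min()
        if d > cutoff:
            retained.append(res)
    return subs_per_position * len(retained), retained
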