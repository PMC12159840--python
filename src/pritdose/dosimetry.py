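"""Absorbed-dose estimation for Lu-177 pretargeted radioimmunotherapy.

The chain implemented here is the standard first-order preclinical beta
dosimetry for a radiohapten whose tissue kinetics are described by a
one-phase decay (decay-corrected, i.e. biological only):

1. Time-integrated activity coefficient (TIAC).  With a(t) the
   fraction-of-injected-dose per gram (= %ID/g / 100) and lambda_p the
   physical decay constant, the TIAC per unit administered activity is

       A_tilde = integral_0^inf a(t) exp(-lambda_p t) dt
               = [ (A0 - P)/(lambda_b + lambda_p) + P/lambda_p ] / 100

   in MBq*h per g per MBq administered.

2. Local-deposition self-dose.  All non-penetrating (electron) energy is
   assumed absorbed where it is emitted; with Delta the mean non-penetrating
   energy per decay converted to Gy*g per MBq*h, the mean absorbed dose
   coefficient is D = A_tilde * Delta (Gy/MBq), reported in cGy/MBq.
   No photon cross-dose, no phantom S-values.

3. Therapeutic index TI = D_tumor / D_tissue, regimen cumulative doses
   (cycles x activity x D), and comparison against organ dose limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biodist import GroupSummary
from .errors import UndefinedStatisticError, ValidationError
from .pk import LN2, OnePhaseDecayFit

#: J per MeV.
_MEV_TO_J = 1.60218e-13
#: decays per MBq*h.
_DECAYS_PER_MBQ_H = 3.6e9


@dataclass(frozen=True)
class NuclideData:
    """Physical data for a therapeutic radionuclide.

    ``mean_np_energy_MeV`` is the mean non-penetrating (electron) energy per
    decay.  ``delta_Gy_g_per_MBq_h`` is the derived local-deposition energy
    factor: 3.6e9 decays/MBq/h x E[MeV] x 1.60218e-13 J/MeV x 1000 g/kg.
    """

    name: str
    t_half_phys_h: float
    mean_np_energy_MeV: float

    def __post_init__(self) -> None:
        if self.t_half_phys_h <= 0:
            raise ValidationError("t_half_phys_h must be > 0")

    @property
    def lambda_phys_per_h(self) -> float:
        return LN2 / self.t_half_phys_h

    @property
    def delta_Gy_g_per_MBq_h(self) -> float:
        return _DECAYS_PER_MBQ_H * self.mean_np_energy_MeV * _MEV_TO_J * 1000.0


#: Lu-177 with the beta mean energy only (0.1335 MeV; T1/2 = 6.65 d).
LU177 = NuclideData(name="Lu-177", t_half_phys_h=159.6, mean_np_energy_MeV=0.1335)
#: Lu-177 including conversion/Auger electrons in the non-penetrating energy.
LU177_TOTAL_NP = NuclideData(name="Lu-177 (total np)", t_half_phys_h=159.6, mean_np_energy_MeV=0.1473)


@dataclass(frozen=True)
class TIAC:
    """Time-integrated activity coefficient for one tissue (MBq*h/g per MBq)."""

    tissue: str
    value_MBq_h_per_g_per_MBq: float
    method: str  # "analytic-from-fit" | "trapezoid-plus-tail"

    def __post_init__(self) -> None:
        v = self.value_MBq_h_per_g_per_MBq
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"TIAC must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class Regimen:
    """A therapy regimen: identical additive cycles of a fixed activity."""

    n_cycles: int
    activity_MBq_per_cycle: float
    cycle_spacing_d: float = 7.0
    pretargeting_interval_h: float = 24.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if self.activity_MBq_per_cycle <= 0:
            raise ValidationError("activity_MBq_per_cycle must be > 0")

    @property
    def total_activity_MBq(self) -> float:
        return self.n_cycles * self.activity_MBq_per_cycle


@dataclass(frozen=True)
class OrganLimit:
    """An organ dose constraint: a hard limit or a soft threshold (Gy)."""

    tissue: str
    limit_Gy: float
    kind: str = "hard-limit"  # "hard-limit" | "threshold"
    note: str = ""

    def __post_init__(self) -> None:
        if self.limit_Gy <= 0:
            raise ValidationError("limit_Gy must be > 0")
        if self.kind not in ("hard-limit", "threshold"):
            raise ValidationError(f"unknown limit kind {self.kind!r}")


class DoseTable:
    """Per-tissue mean absorbed dose coefficients and therapeutic indices.

    Thin wrapper over a DataFrame with columns ``tissue`` and
    ``dose_cGy_per_MBq``; the tumor row anchors the TI column.
    """

    def __init__(
        self,
        doses: Mapping[str, float] | pd.DataFrame,
        *,
        tumor_tissue: str = "tumor",
        radiohapten: str = "",
        pretargeting_interval_h: float | None = None,
    ):
        if isinstance(doses, pd.DataFrame):
            frame = doses[["tissue", "dose_cGy_per_MBq"]].copy()
        else:
            frame = pd.DataFrame(
                {"tissue": list(doses), "dose_cGy_per_MBq": list(doses.values())}
            )
        if (frame["dose_cGy_per_MBq"] < 0).any():
            raise ValidationError("dose coefficients must be >= 0")
        self.frame = frame.reset_index(drop=True)
        self.tumor_tissue = tumor_tissue
        self.radiohapten = radiohapten
        self.pretargeting_interval_h = pretargeting_interval_h

    def dose(self, tissue: str) -> float:
        sel = self.frame.loc[self.frame["tissue"] == tissue, "dose_cGy_per_MBq"]
        if sel.empty:
            raise KeyError(f"no dose coefficient for tissue {tissue!r}")
        return float(sel.iloc[0])

    @property
    def tissues(self) -> list[str]:
        return list(self.frame["tissue"])

    def with_ti(self) -> pd.DataFrame:
        """Frame with exact TI and its printed-integer presentation; the
        tumor row's TI is blank."""
        d_tumor = self.dose(self.tumor_tissue)
        rows = []
        for tissue in self.tissues:
            if tissue == self.tumor_tissue:
                rows.append((tissue, self.dose(tissue), None, None))
            else:
                ti = therapeutic_index(self, tissue)
                rows.append((tissue, self.dose(tissue), ti, present_ti(ti)))
        out = pd.DataFrame(
            rows, columns=["tissue", "dose_cGy_per_MBq", "ti", "ti_presented"]
        )
        out.attrs["tumor_dose_cGy_per_MBq"] = d_tumor
        return out

    def to_csv(self, path: str | Path) -> None:
        self.with_ti().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TIAC and dose coefficients
# ---------------------------------------------------------------------------

def tiac_from_fit(
    fit: OnePhaseDecayFit, nuclide: NuclideData, *, tissue: str = ""
) -> TIAC:
    """Closed-form TIAC of a one-phase-decay tissue under physical decay."""
    lam_b = fit.lambda_bio_per_h
    lam_p = nuclide.lambda_phys_per_h
    if lam_p <= 0 and fit.plateau > 0:
        raise ValidationError("divergent integral: plateau > 0 with no physical decay")
    plateau_term = fit.plateau / lam_p if fit.plateau > 0 else 0.0
    value = ((fit.A0 - fit.plateau) / (lam_b + lam_p) + plateau_term) / 100.0
    return TIAC(tissue=tissue, value_MBq_h_per_g_per_MBq=value, method="analytic-from-fit")


def tiac_trapezoid_tail(
    summary: Sequence[GroupSummary],
    fit: OnePhaseDecayFit,
    nuclide: NuclideData,
    *,
    tissue: str = "",
) -> TIAC:
    """Hybrid TIAC: trapezoid-style integral over the observed means plus an
    analytic tail from the fitted curve beyond the last timepoint.

    The activity concentration is taken piecewise-linear between observed
    means (%ID/g / 100); each segment is integrated against the exact
    physical-decay weight exp(-lambda_p t) in closed form, which removes the
    decay-weighting component of the discretization error.  The segment from
    t = 0 to the first sample uses the back-extrapolated fit value A0.
    """
    pts = sorted(((s.time_h, s.mean_pct_id_g) for s in summary), key=lambda p: p[0])
    if len(pts) < 2:
        raise ValidationError("need >= 2 observed timepoints")
    lam_p = nuclide.lambda_phys_per_h
    lam_b = fit.lambda_bio_per_h
    t = np.array([0.0] + [p[0] for p in pts])
    a = np.array([fit.A0] + [p[1] for p in pts]) / 100.0

    def _segment(t0: float, a0: float, t1: float, a1: float) -> float:
        # integral of (c + d*t) exp(-lam_p t) over [t0, t1]
        d = (a1 - a0) / (t1 - t0)
        c = a0 - d * t0

        def antideriv(tt: float) -> float:
            return -((c + d * tt) / lam_p + d / lam_p**2) * math.exp(-lam_p * tt)

        return antideriv(t1) - antideriv(t0)

    body = sum(
        _segment(t[i], a[i], t[i + 1], a[i + 1]) for i in range(len(t) - 1)
    )
    t_last = t[-1]
    tail = (
        (fit.A0 - fit.plateau) * math.exp(-(lam_b + lam_p) * t_last) / (lam_b + lam_p)
        + fit.plateau * math.exp(-lam_p * t_last) / lam_p
    ) / 100.0
    return TIAC(
        tissue=tissue,
        value_MBq_h_per_g_per_MBq=body + tail,
        method="trapezoid-plus-tail",
    )


def dose_coefficient(tiac: TIAC, nuclide: NuclideData) -> float:
    """Mean absorbed dose coefficient in cGy/MBq from a TIAC: A_tilde x Delta
    (Gy/MBq) x 100, assuming local deposition of non-penetrating energy."""
    return tiac.value_MBq_h_per_g_per_MBq * nuclide.delta_Gy_g_per_MBq_h * 100.0


# ---------------------------------------------------------------------------
# Therapeutic indices, regimens, limits
# ---------------------------------------------------------------------------

def therapeutic_index(dose_table: DoseTable, tissue: str) -> float:
    """TI = D_tumor / D_tissue (unrounded; see present_ti for the integer
    presentation convention)."""
    d_tissue = dose_table.dose(tissue)
    if d_tissue <= 0:
        raise UndefinedStatisticError(f"TI undefined: zero dose for {tissue!r}")
    return dose_table.dose(dose_table.tumor_tissue) / d_tissue


def present_ti(ti: float) -> int:
    """Round a TI to the nearest integer, halves away from zero."""
    return int(math.floor(ti + 0.5)) if ti >= 0 else -int(math.floor(-ti + 0.5))


def two_sigfigs(x: float) -> float:
    """Round to two significant figures (presentation of cumulative doses)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + 1)


def cumulative_dose(regimen: Regimen, dose_coeff_cGy_per_MBq: float) -> float:
    """Cumulative absorbed dose in Gy over all cycles of a regimen:
    n_cycles x activity x coefficient / 100 (cycles are additive)."""
    if dose_coeff_cGy_per_MBq < 0:
        raise ValidationError("dose coefficient must be >= 0")
    return regimen.total_activity_MBq * dose_coeff_cGy_per_MBq / 100.0


def blood_surrogate_marrow(blood_coeff_cGy_per_MBq: float, factor: float = 1.0) -> float:
    """Bone-marrow dose coefficient using blood activity concentration as a
    surrogate, scaled by a marrow-to-blood factor (default 1.0)."""
    if factor <= 0:
        raise ValidationError(f"factor must be > 0, got {factor}")
    return blood_coeff_cGy_per_MBq * factor


def limit_report(
    projections: Mapping[str, float], limits: Sequence[OrganLimit]
) -> pd.DataFrame:
    """Compare projected organ doses (Gy) against limits.

    Status per tissue: 'below' when projection < limit; for threshold-kind
    limits 'reached' once projection >= limit; for hard limits 'reached' at
    equality and 'exceeded' above.  Tissues without a limit are listed as
    'unconstrained'.  Margin = limit - projection (Gy; NaN if unconstrained).
    """
    if not limits:
        raise ValidationError("limits must be non-empty")
    by_tissue = {l.tissue: l for l in limits}
    rows = []
    for tissue, proj in projections.items():
        lim = by_tissue.get(tissue)
        if lim is None:
            rows.append((tissue, proj, None, None, "unconstrained", float("nan")))
            continue
        if proj < lim.limit_Gy:
            status = "below"
        elif lim.kind == "threshold":
            status = "reached"
        else:
            status = "reached" if proj == lim.limit_Gy else "exceeded"
        rows.append((tissue, proj, lim.limit_Gy, lim.kind, status, lim.limit_Gy - proj))
    return pd.DataFrame(
        rows,
        columns=["tissue", "projection_Gy", "limit_Gy", "kind", "status", "margin_Gy"],
    )


# ---------------------------------------------------------------------------
# Packaged reference coefficients (study dose table) and default limits
# ---------------------------------------------------------------------------

def reference_dose_table(
    radiohapten: str = "Gemini", pretargeting_interval_h: float = 48
) -> DoseTable:
    """Load the packaged reference mean absorbed dose coefficients for the
    SW1222-luc orthotopic liver model (mono- and bivalent Lu-177 radiohaptens
    at 24 h / 48 h pretargeting intervals), as a DoseTable."""
    df = load_reference_coefficients()
    sel = df[
        (df["radiohapten"] == radiohapten)
        & (df["pretargeting_interval_h"] == pretargeting_interval_h)
    ]
    if sel.empty:
        raise KeyError(
            f"no reference coefficients for {radiohapten!r} at "
            f"{pretargeting_interval_h} h"
        )
    return DoseTable(
        sel[["tissue", "dose_cGy_per_MBq"]],
        tumor_tissue="tumor",
        radiohapten=radiohapten,
        pretargeting_interval_h=pretargeting_interval_h,
    )


def load_reference_coefficients() -> pd.DataFrame:
    """Long-format reference coefficient table (all radiohaptens/intervals),
    including the published integer TI for each non-tumor row."""
    with resources.files("pritdose.data").joinpath("dose_coefficients_sw1222.csv").open() as fh:
        return pd.read_csv(fh)


def default_organ_limits() -> list[OrganLimit]:
    """Organ constraints used in the study projections: kidney hard limit of
    23 Gy (lower edge of the accepted 23-26 Gy radiopharmaceutical-therapy
    range), marrow threshold 2.5 Gy, ovarian follicle LD50 threshold 4 Gy,
    uterine pregnancy-function threshold 4 Gy."""
    with resources.files("pritdose.data").joinpath("organ_limits.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        OrganLimit(tissue=r.tissue, limit_Gy=float(r.limit_Gy), kind=r.kind, note=r.note)
        for r in df.itertuples(index=False)
    ]
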