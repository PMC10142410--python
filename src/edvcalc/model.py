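"""Closed-form pieces of the EDV estimation chain.

The method estimates left-ventricular end-diastolic volume (EDV) from
noninvasive measurements only: cuff systolic/diastolic pressure, the
pre-ejection period (PEP), the ejection time (ET), and stroke volume (SV).
Its physiological backbone is ventricular-arterial coupling, the ratio of
end-systolic elastance Ees (ventricular contractility) to effective arterial
elastance Ea (arterial load).  Four closed-form relations are implemented
here:

* an empirical linear regression of end-systolic pressure Pes on cuff SBP
  and DBP,
* the bilinear-elastance expression for the hypothetical peak isovolumic
  pressure Pmax = Pad·[1 + (ET/PEP)·k],
* the coupling identity Ees/Ea = (Pmax − Pes)/Pes,
* the volume identity EDV = SV·(1 + Ea/Ees) + V0, with V0 (the unstressed
  volume at zero end-systolic pressure) assumed 0 ml for normal hearts.

All pressures are mmHg, all times ms, all volumes ml.  Only the ratio
ET/PEP enters any equation, so the time unit cancels; milliseconds are the
canonical storage unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PES_SBP_COEF",
    "PES_DBP_COEF",
    "PES_INTERCEPT",
    "K_COEF",
    "K_EXP",
    "BeatObservation",
    "CouplingSolution",
    "EDVEstimate",
    "InvalidInputError",
    "estimate_pes",
    "pmax_from_timings",
    "coupling_from_pressures",
    "estimate_edv",
]

# Empirical Pes regression on cuff pressures (mmHg).
PES_SBP_COEF = 0.205
PES_DBP_COEF = 0.898
PES_INTERCEPT = 0.4214

# Empirical bilinear-elastance slope ratio: k = K_COEF * (Ees/Ea)**K_EXP.
K_COEF = 0.53
K_EXP = 0.51


class InvalidInputError(ValueError):
    """A physiological input violates its validity contract."""


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise InvalidInputError(f"{name} must be > 0, got {value!r}")


@dataclass
class BeatObservation:
    """One subject's (or beat's) measured noninvasive inputs.

    Fields may be ``None`` to represent missing measurements from a raw
    table; :meth:`validate` enforces the physiological contract and
    :meth:`missing_fields` reports what is absent.  ``edv_ref`` is an
    optional reference EDV (e.g. echocardiographic) used only for method
    comparison, never in the estimate itself.
    """

    subject_id: str
    sbp: Optional[float] = None     # systolic cuff pressure, mmHg
    dbp: Optional[float] = None     # diastolic cuff pressure, mmHg
    pep: Optional[float] = None     # pre-ejection period, ms
    et: Optional[float] = None      # ejection time, ms
    sv: Optional[float] = None      # stroke volume, ml
    edv_ref: Optional[float] = None  # reference EDV, ml (optional)

    REQUIRED = ("sbp", "dbp", "pep", "et", "sv")

    def missing_fields(self) -> list[str]:
        return [f for f in self.REQUIRED if getattr(self, f) is None]

    def validate(self) -> None:
        missing = self.missing_fields()
        if missing:
            raise InvalidInputError(
                f"subject {self.subject_id!r}: missing required fields {missing}"
            )
        _require_positive(self.dbp, "dbp")
        _require_positive(self.pep, "pep")
        _require_positive(self.et, "et")
        _require_positive(self.sv, "sv")
        if not self.sbp > self.dbp:
            raise InvalidInputError(
                f"subject {self.subject_id!r}: sbp ({self.sbp}) must exceed dbp ({self.dbp})"
            )
        if self.edv_ref is not None and not self.edv_ref > self.sv:
            raise InvalidInputError(
                f"subject {self.subject_id!r}: edv_ref ({self.edv_ref}) must exceed "
                f"sv ({self.sv}) — end-systolic volume must be positive"
            )

    @property
    def complete(self) -> bool:
        return not self.missing_fields()


@dataclass
class CouplingSolution:
    """Solved ventricular-arterial coupling with solver diagnostics.

    ``ees_over_ea`` is the coupling ratio; ``k`` the bilinear elastance
    slope ratio consistent with it; ``pes``/``pmax`` the end-systolic and
    peak isovolumic pressures (mmHg).  ``residual`` is the value of the
    coupling equation's residual at the returned root (dimensionless).
    """

    ees_over_ea: float
    k: float
    pes: float
    pmax: float
    iterations: int = 0
    converged: bool = False
    residual: float = float("nan")
    used_fallback: bool = False


@dataclass
class EDVEstimate:
    """Estimated end-diastolic and end-systolic volumes (ml)."""

    edv_calc: float
    esv_calc: float
    coupling: Optional[CouplingSolution] = field(default=None, repr=False)


def estimate_pes(sbp: float, dbp: float, *, validate: bool = True) -> float:
    """End-systolic arterial pressure (mmHg) from cuff pressures.

    Linear regression ``Pes = 0.205·SBP + 0.898·DBP + 0.4214``.  For
    physiological inputs the result lies strictly between DBP and SBP.

    ``validate=False`` disables the precondition check (contract testing
    only).
    """
    if validate:
        _require_positive(dbp, "dbp")
        if not sbp > dbp:
            raise InvalidInputError(f"sbp ({sbp}) must exceed dbp ({dbp})")
    return PES_SBP_COEF * sbp + PES_DBP_COEF * dbp + PES_INTERCEPT


def pmax_from_timings(
    pad: float, et: float, pep: float, k: float, *, validate: bool = True
) -> float:
    """Peak isovolumic pressure Pmax = Pad·[1 + (ET/PEP)·k] (mmHg).

    ``pad`` is the diastolic (ejection-onset) pressure; ``k`` the bilinear
    elastance slope ratio.  Strictly increasing in pad, et and k; strictly
    decreasing in pep.
    """
    if validate:
        _require_positive(pad, "pad")
        _require_positive(et, "et")
        _require_positive(pep, "pep")
        if k < 0:
            raise InvalidInputError(f"k must be >= 0, got {k!r}")
    if pep == 0:
        raise InvalidInputError("pep must be nonzero (ET/PEP undefined)")
    return pad * (1.0 + (et / pep) * k)


def coupling_from_pressures(pmax: float, pes: float, *, validate: bool = True) -> float:
    """Coupling ratio Ees/Ea = (Pmax − Pes)/Pes (dimensionless)."""
    if validate:
        _require_positive(pes, "pes")
    elif pes == 0:
        raise InvalidInputError("pes must be nonzero")
    return (pmax - pes) / pes


def estimate_edv(
    sv: float,
    ees_over_ea: float,
    v0: float = 0.0,
    coupling: Optional[CouplingSolution] = None,
    *,
    validate: bool = True,
) -> EDVEstimate:
    """End-diastolic volume from stroke volume and coupling.

    ``EDV = SV·(1 + Ea/Ees) + V0``; equivalently ESV − V0 = SV/(Ees/Ea).
    ``v0`` (unstressed volume, ml) defaults to 0, the stated assumption for
    hearts with normal systolic function; it is exposed for sensitivity
    analysis.
    """
    if validate:
        _require_positive(sv, "sv")
        _require_positive(ees_over_ea, "ees_over_ea")
        if v0 < 0:
            raise InvalidInputError(f"v0 must be >= 0, got {v0!r}")
    edv = sv * (1.0 + 1.0 / ees_over_ea) + v0
    return EDVEstimate(edv_calc=edv, esv_calc=edv - sv, coupling=coupling)
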