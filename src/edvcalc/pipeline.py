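"""Per-subject estimation chain and cohort-level exclusion filtering.

The chain for one subject: cuff pressures → Pes (linear regression) →
Ees/Ea (Newton solve of the coupling equations, with Pad taken as the cuff
DBP) → EDV = SV·(1 + Ea/Ees).  Exclusion filtering marks — never drops —
records with missing data or a volume at/above the configured limit
(140 ml by default, the normal-range cutoff used for healthy cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .model import BeatObservation, CouplingSolution, EDVEstimate, estimate_edv, estimate_pes
from .solver import SolverConfig, solve_coupling

__all__ = [
    "SubjectResult",
    "EstimationError",
    "estimate_subject",
    "estimate_cohort",
    "apply_exclusions",
    "EDV_EXCLUSION_LIMIT",
]

# Volume cutoff (ml): subjects at or above it fall outside the normal range
# the method was validated on.
EDV_EXCLUSION_LIMIT = 140.0


class EstimationError(RuntimeError):
    """Estimation failed for a subject; message carries the subject id."""


@dataclass
class SubjectResult:
    observation: BeatObservation
    coupling: Optional[CouplingSolution] = None
    estimate: Optional[EDVEstimate] = None
    excluded: bool = False
    exclusion_reason: str = ""


def estimate_subject(
    obs: BeatObservation,
    config: SolverConfig | None = None,
    v0: float = 0.0,
) -> SubjectResult:
    """Run the full estimation chain for one observation.

    All intermediates (Pes, Pmax, k, Ees/Ea, solver diagnostics) are
    retained on the returned result for audit.  Solver failures are
    re-raised as :class:`EstimationError` naming the subject.
    """
    obs.validate()
    try:
        pes = estimate_pes(obs.sbp, obs.dbp)
        coupling = solve_coupling(obs.dbp, pes, obs.et, obs.pep, config)
        estimate = estimate_edv(obs.sv, coupling.ees_over_ea, v0=v0, coupling=coupling)
    except Exception as exc:
        raise EstimationError(f"subject {obs.subject_id!r}: {exc}") from exc
    return SubjectResult(observation=obs, coupling=coupling, estimate=estimate)


def estimate_cohort(
    observations: Iterable[BeatObservation],
    config: SolverConfig | None = None,
    v0: float = 0.0,
) -> list[SubjectResult]:
    """Estimate every complete observation; mark incomplete ones excluded.

    Records with missing required fields are carried through as excluded
    results ("missing data") rather than raising, matching the study's
    intent of reporting how many records the filters removed.  Subjects
    whose measurements admit no coupling solution (mutually inconsistent
    pressures/timings, which noisy data can produce) are likewise marked
    excluded instead of aborting the cohort.
    """
    results: list[SubjectResult] = []
    for obs in observations:
        if not obs.complete:
            results.append(
                SubjectResult(
                    observation=obs,
                    excluded=True,
                    exclusion_reason=f"missing data: {', '.join(obs.missing_fields())}",
                )
            )
        else:
            try:
                results.append(estimate_subject(obs, config, v0=v0))
            except EstimationError as exc:
                results.append(
                    SubjectResult(
                        observation=obs,
                        excluded=True,
                        exclusion_reason=f"estimation failed: {exc}",
                    )
                )
    return results


def _volume_value(result: SubjectResult, field: str) -> Optional[float]:
    if field == "edv_ref":
        return result.observation.edv_ref
    if field == "sv":
        return result.observation.sv
    raise ValueError(f"unknown exclusion field {field!r}; use 'edv_ref' or 'sv'")


def apply_exclusions(
    results: Sequence[SubjectResult],
    edv_limit: float = EDV_EXCLUSION_LIMIT,
    volume_field: str = "edv_ref",
) -> list[SubjectResult]:
    """Flag records with missing data or volume >= ``edv_limit``.

    ``volume_field`` selects which measured volume the cutoff applies to
    ("edv_ref", the reference EDV, or "sv").  The boundary is inclusive:
    a value exactly at the limit is excluded.  Returns a new list in the
    input order with every record present and flags set; idempotent.
    """
    out: list[SubjectResult] = []
    for r in results:
        missing = r.observation.missing_fields()
        volume = _volume_value(r, volume_field)
        if r.excluded and r.estimate is None and not missing:
            # estimation failure recorded upstream: keep the flag verbatim
            out.append(replace(r))
            continue
        if missing:
            out.append(
                replace(
                    r,
                    excluded=True,
                    exclusion_reason=f"missing data: {', '.join(missing)}",
                )
            )
        elif volume is not None and volume >= edv_limit:
            out.append(
                replace(
                    r,
                    excluded=True,
                    exclusion_reason=f"{volume_field} {volume:g} ml >= limit {edv_limit:g} ml",
                )
            )
        else:
            out.append(replace(r, excluded=False, exclusion_reason=""))
    return out
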