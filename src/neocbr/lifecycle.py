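"""Revise/retain lifecycle: temporary storage, outcomes, promotion.

A solved case is not added to the permanent case base immediately.  It is
held in a temporary store together with the system's prediction (and, when
the clinician rejected that prediction, the expert's own solution) until the
neonate's actual discharge status is known.  Only then is the case — with
the *actual* outcome as its solution — committed to the permanent case base,
so the system only remembers valid cases.  Committing invalidates the fitted
min-max bounds, which must be refitted before the next retrieval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

from .case_model import Case, CaseBase, ValidationError
from .retrieval import Prediction

__all__ = ["PendingCase", "Journal", "submit", "record_outcome", "commit"]

AWAITING = "awaiting_outcome"
READY = "ready"
COMMITTED = "committed"


@dataclass
class PendingCase:
    """A solved case parked in the temporary store.

    Keeps the full audit trail: the system's prediction, the expert's
    replacement solution when the prediction was not approved, and the
    actual outcome once recorded.
    """

    case: Case
    system_prediction: Prediction
    expert_solution: Union[str, int, None] = None
    actual_outcome: Union[str, int, None] = None
    state: str = AWAITING

    @property
    def working_solution(self) -> Union[str, int]:
        """The solution in force before discharge: the expert's if the
        prediction was unapproved, the system's otherwise."""
        if self.system_prediction.approval == "unapproved":
            return self.expert_solution
        return self.system_prediction.value


def submit(
    case: Case,
    pred: Prediction,
    approved: bool,
    expert_solution: Union[str, int, None] = None,
) -> PendingCase:
    """Park a solved case in the temporary store.

    An unapproved prediction must come with the neonatologist's own
    solution; an approved one carries the system's.
    """
    if not approved and expert_solution is None:
        raise ValidationError("an unapproved prediction requires an expert solution")
    pred = replace(pred, approval="approved" if approved else "unapproved")
    status = "temporary_approved" if approved else "temporary_unapproved"
    pending = replace(case, status=status)
    return PendingCase(
        case=pending,
        system_prediction=pred,
        expert_solution=None if approved else expert_solution,
    )


def record_outcome(pc: PendingCase, actual: Union[str, int]) -> PendingCase:
    """Record the neonate's real discharge outcome; the case becomes ready
    for promotion.  Recording twice is an error."""
    if pc.state != AWAITING:
        raise ValidationError(f"outcome already recorded (state={pc.state!r})")
    if isinstance(actual, int) and actual < 0:
        raise ValidationError("LOS outcome must be >= 0")
    pc.actual_outcome = actual
    pc.state = READY
    return pc


def commit(pc: PendingCase, cb: CaseBase) -> CaseBase:
    """Promote a ready case to the permanent case base.

    The committed case stores the actual outcome as its solution.  The case
    base's fitted statistics are flagged stale: bounds must be refitted
    before the next retrieval sees the new case.
    """
    if pc.state != READY:
        raise ValidationError(f"cannot commit a case in state {pc.state!r}")
    promoted = replace(pc.case, status="permanent", outcome=pc.actual_outcome)
    cb.cases.append(promoted)
    cb.mark_stale()
    pc.state = COMMITTED
    return cb


class Journal:
    """JSON-file persistence for the temporary store."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        self.entries: dict[str, PendingCase] = {}
        if self.path.exists():
            self._load()

    def add(self, pc: PendingCase) -> None:
        self.entries[pc.case.id] = pc
        self.save()

    def get(self, case_id: str) -> PendingCase:
        return self.entries[case_id]

    def save(self) -> None:
        payload = []
        for pc in self.entries.values():
            payload.append(
                {
                    "case": {
                        "id": pc.case.id,
                        "values": pc.case.values,
                        "status": pc.case.status,
                    },
                    "prediction": {
                        "task": pc.system_prediction.task,
                        "value": pc.system_prediction.value,
                        "neighbor_ids": pc.system_prediction.neighbor_ids,
                        "approval": pc.system_prediction.approval,
                    },
                    "expert_solution": pc.expert_solution,
                    "actual_outcome": pc.actual_outcome,
                    "state": pc.state,
                }
            )
        self.path.write_text(json.dumps(payload, indent=2))

    def _load(self) -> None:
        for e in json.loads(self.path.read_text()):
            case = Case(id=e["case"]["id"], values=e["case"]["values"], status=e["case"]["status"])
            pred = Prediction(
                task=e["prediction"]["task"],
                value=e["prediction"]["value"],
                neighbor_ids=e["prediction"]["neighbor_ids"],
                approval=e["prediction"]["approval"],
            )
            self.entries[case.id] = PendingCase(
                case=case,
                system_prediction=pred,
                expert_solution=e["expert_solution"],
                actual_outcome=e["actual_outcome"],
                state=e["state"],
            )
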