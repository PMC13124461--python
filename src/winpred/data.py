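"""Subject-level data model for prioritized composite time-to-event outcomes.

A subject's history is a sequence of dated events: zero or more nonfatal
events followed by a single terminal record, which is either a death or a
censoring.  Pairwise win/loss comparisons prioritize death over the first
nonfatal event, so the analysis-ready representation keeps, per subject,

* ``X`` -- the last observation time (death or censoring time),
* a death indicator,
* the first nonfatal event time (if any),
* the covariate vector and an optional stratum label.

Later nonfatal events are retained verbatim for alternative win rules but
play no role in the default comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositeDataError",
    "SubjectRecord",
    "CohortData",
    "StatusCoding",
    "parse_long_records",
    "read_long_csv",
    "derive_tfe",
]


class CompositeDataError(ValueError):
    """Raised when long-format records violate the composite-outcome contract."""


@dataclass(frozen=True)
class StatusCoding:
    """Mapping of integer status codes in long-format files.

    Defaults follow the convention used by existing win-ratio datasets:
    0 = censoring, 1 = death, 2 = nonfatal event.
    """

    censor: int = 0
    death: int = 1
    nonfatal: int = 2

    def __post_init__(self) -> None:
        if len({self.censor, self.death, self.nonfatal}) != 3:
            raise CompositeDataError("status codes must be distinct")


@dataclass
class SubjectRecord:
    """One subject's covariates and ordered event history.

    ``events`` is a sequence of ``(time, kind)`` with ``kind`` one of
    ``"death"``, ``"nonfatal"``, ``"censor"``; the last entry must be the
    terminal record (death or censoring) and times must be nondecreasing.
    """

    subject_id: object
    covariates: np.ndarray
    events: tuple[tuple[float, str], ...]
    stratum: object = 0

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim != 1:
            raise CompositeDataError(f"subject {self.subject_id}: covariates must be a vector")
        if not np.all(np.isfinite(self.covariates)):
            raise CompositeDataError(f"subject {self.subject_id}: non-finite covariate value")
        self.events = tuple((float(t), str(k)) for t, k in self.events)
        self._validate_events()

    def _validate_events(self) -> None:
        sid = self.subject_id
        if not self.events:
            raise CompositeDataError(f"subject {sid}: no event records")
        times = [t for t, _ in self.events]
        kinds = [k for _, k in self.events]
        for k in kinds:
            if k not in ("death", "nonfatal", "censor"):
                raise CompositeDataError(f"subject {sid}: unknown event kind {k!r}")
        if any(t < 0 for t in times):
            raise CompositeDataError(f"subject {sid}: negative event time")
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise CompositeDataError(f"subject {sid}: event times not nondecreasing")
        if kinds[-1] not in ("death", "censor"):
            raise CompositeDataError(f"subject {sid}: missing terminal (death/censor) record")
        if any(k in ("death", "censor") for k in kinds[:-1]):
            raise CompositeDataError(f"subject {sid}: event recorded after a terminal record")
        if times[-1] <= 0:
            raise CompositeDataError(f"subject {sid}: zero follow-up (terminal time must be > 0)")

    @property
    def follow_up(self) -> float:
        """Last observation time X = D ∧ C."""
        return self.events[-1][0]

    @property
    def death(self) -> bool:
        return self.events[-1][1] == "death"

    @property
    def first_nonfatal(self) -> float | None:
        for t, k in self.events:
            if k == "nonfatal":
                return t
        return None

    @property
    def nonfatal_times(self) -> tuple[float, ...]:
        return tuple(t for t, k in self.events if k == "nonfatal")


class CohortData:
    """Validated cohort of :class:`SubjectRecord` with array views for analysis.

    Array attributes (all length ``n``, aligned):

    ``ids``             subject identifiers (object array)
    ``Z``               (n, p) covariate matrix
    ``X``               last observation time
    ``death``           terminal-event-is-death indicator
    ``first_nonfatal``  first nonfatal time, ``nan`` when absent
    ``strata``          integer stratum codes into ``stratum_labels``
    """

    def __init__(self, subjects: Sequence[SubjectRecord]):
        subjects = list(subjects)
        if not subjects:
            raise CompositeDataError("cohort is empty")
        p = subjects[0].covariates.size
        for s in subjects:
            if s.covariates.size != p:
                raise CompositeDataError(
                    f"subject {s.subject_id}: covariate length {s.covariates.size} != {p}"
                )
        seen: set = set()
        for s in subjects:
            if s.subject_id in seen:
                raise CompositeDataError(f"duplicate subject id {s.subject_id!r}")
            seen.add(s.subject_id)
        self.subjects = subjects
        self.p = p
        self.ids = np.array([s.subject_id for s in subjects], dtype=object)
        self.Z = np.vstack([s.covariates for s in subjects]) if p else np.empty((len(subjects), 0))
        self.X = np.array([s.follow_up for s in subjects], dtype=float)
        self.death = np.array([s.death for s in subjects], dtype=bool)
        fnf = [s.first_nonfatal for s in subjects]
        self.first_nonfatal = np.array(
            [np.nan if t is None else t for t in fnf], dtype=float
        )
        labels = sorted({s.stratum for s in subjects}, key=repr)
        self.stratum_labels = labels
        lab_ix = {lab: i for i, lab in enumerate(labels)}
        self.strata = np.array([lab_ix[s.stratum] for s in subjects], dtype=int)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def n_strata(self) -> int:
        return len(self.stratum_labels)

    def fingerprint(self) -> str:
        """Stable digest of (n, Z, X) used to guard against mixing fits."""
        h = hashlib.sha1()
        h.update(np.int64(self.n).tobytes())
        h.update(np.ascontiguousarray(self.Z).tobytes())
        h.update(np.ascontiguousarray(self.X).tobytes())
        return h.hexdigest()

    def to_long_frame(
        self,
        coding: StatusCoding = StatusCoding(),
        id_col: str = "id",
        time_col: str = "time",
        status_col: str = "status",
        covariate_cols: Sequence[str] | None = None,
        stratum_col: str | None = None,
    ) -> pd.DataFrame:
        """Serialize to the long format accepted by :func:`parse_long_records`."""
        if covariate_cols is None:
            covariate_cols = [f"z{k + 1}" for k in range(self.p)]
        code = {"censor": coding.censor, "death": coding.death, "nonfatal": coding.nonfatal}
        rows = []
        multi_strata = self.n_strata > 1 or stratum_col is not None
        for s in self.subjects:
            for t, k in s.events:
                row = {id_col: s.subject_id, time_col: t, status_col: code[k]}
                row.update(dict(zip(covariate_cols, s.covariates)))
                if multi_strata:
                    row[stratum_col or "stratum"] = s.stratum
                rows.append(row)
        return pd.DataFrame(rows)


def parse_long_records(
    rows: pd.DataFrame,
    coding: StatusCoding = StatusCoding(),
    id_col: str = "id",
    time_col: str = "time",
    status_col: str = "status",
    covariate_cols: Sequence[str] | None = None,
    stratum_col: str | None = None,
) -> CohortData:
    """Convert a long-format table into a validated :class:`CohortData`.

    Each row is one event ``(id, time, status, covariates...)``; rows are
    sorted by ``(id, time)`` before assembly, covariates must be constant
    within a subject, and every subject must end with exactly one terminal
    (death or censoring) record.
    """
    for col in (id_col, time_col, status_col):
        if col not in rows.columns:
            raise CompositeDataError(f"missing required column {col!r}")
    if covariate_cols is None:
        reserved = {id_col, time_col, status_col, stratum_col}
        covariate_cols = [c for c in rows.columns if c not in reserved]
    kind_of = {coding.censor: "censor", coding.death: "death", coding.nonfatal: "nonfatal"}

    subjects = []
    for sid, grp in rows.groupby(id_col, sort=True):
        grp = grp.sort_values(time_col, kind="stable")
        zmat = grp[list(covariate_cols)].to_numpy(dtype=float)
        if len(grp) > 1 and not np.allclose(zmat, zmat[0], equal_nan=False):
            raise CompositeDataError(f"subject {sid}: covariates vary across rows")
        events = []
        for t, code in zip(grp[time_col], grp[status_col]):
            try:
                kind = kind_of[int(code)]
            except (KeyError, ValueError):
                raise CompositeDataError(
                    f"subject {sid}: unknown status code {code!r}"
                ) from None
            events.append((float(t), kind))
        stratum = grp[stratum_col].iloc[0] if stratum_col is not None else 0
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                covariates=zmat[0] if covariate_cols else np.empty(0),
                events=tuple(events),
                stratum=stratum,
            )
        )
    return CohortData(subjects)


def read_long_csv(path, sep: str = ",", **kwargs) -> CohortData:
    """Read a delimited long-format event file (header required)."""
    return parse_long_records(pd.read_csv(path, sep=sep), **kwargs)


def derive_tfe(cohort: CohortData) -> pd.DataFrame:
    """Reduce the composite outcome to time-to-first-event (TFE) data.

    With death prioritized over one nonfatal event, the tie-breaking first
    event is ``T̃ = D ∧ T``, observed as ``X̃ = min(first nonfatal, X)`` with
    event indicator ``δ̃ = 1`` iff a death or nonfatal event occurred at X̃.
    Returns a frame with columns ``id, time, status, stratum`` plus the
    covariates.
    """
    has_nf = ~np.isnan(cohort.first_nonfatal)
    x_tilde = np.where(has_nf, cohort.first_nonfatal, cohort.X)
    # no nonfatal event: first event is the death itself, if observed
    delta = np.where(has_nf, 1, cohort.death.astype(int))
    out = pd.DataFrame({"id": cohort.ids, "time": x_tilde, "status": delta,
                        "stratum": cohort.strata})
    for k in range(cohort.p):
        out[f"z{k + 1}"] = cohort.Z[:, k]
    return out
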