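"""Domain types, file I/O, report reconciliation, and the hosting/observability panel.

The raw unit of data is an *interview*: a family reports, on a given day, the
social events (hosting a drinking party, or attending one as a guest) that it
took part in during the two days preceding the interview.  From a collection
of interviews we build an :class:`EventPanel` — binary tensors ``h[i, j, t]``
(family *i* observed hosting family *j* on day *t*) and ``o[i, j, t]`` (the
cell was *potentially* observable: at least one of the two families completed
an interview covering day *t*).  All downstream estimators are corrected for
this observation window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: number of days preceding an interview that the interview covers
RECALL_DAYS = 2

#: window (days) within which a host-reported and a guest-reported date are
#: treated as divergent reports of the same event
DIVERGENT_DATE_WINDOW = 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyRecord:
    """A nuclear family: the node of the social network."""

    family_id: str
    member_ids: tuple[str, ...]
    head_ages: tuple[float, ...]
    location: tuple[float, float]  # (latitude, longitude) decimal degrees

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError(f"family {self.family_id} has no members")
        if len(self.head_ages) not in (1, 2):
            raise ValueError(
                f"family {self.family_id}: expected 1 or 2 head ages, "
                f"got {len(self.head_ages)}"
            )
        lat, lon = self.location
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"family {self.family_id}: invalid coordinates {self.location}")

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def head_age(self) -> float:
        """Mean age of the household heads."""
        return float(np.mean(self.head_ages))


@dataclass(frozen=True)
class PedigreeEntry:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    family_id: str
    sex: str | None = None


@dataclass
class Village:
    """Families, members and the day grid of the study."""

    families: list[FamilyRecord]
    individuals: list[PedigreeEntry]
    study_days: int

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("village has zero families")
        fam_ids = [f.family_id for f in self.families]
        if len(set(fam_ids)) != len(fam_ids):
            dupes = sorted({x for x in fam_ids if fam_ids.count(x) > 1})
            raise ValueError(f"duplicate family ids: {dupes}")
        ind_ids = [p.individual_id for p in self.individuals]
        if len(set(ind_ids)) != len(ind_ids):
            dupes = sorted({x for x in ind_ids if ind_ids.count(x) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        membership: dict[str, str] = {}
        for f in self.families:
            for m in f.member_ids:
                if m in membership:
                    raise ValueError(
                        f"individual {m} belongs to families "
                        f"{membership[m]} and {f.family_id}"
                    )
                membership[m] = f.family_id
        _check_pedigree_acyclic(self.individuals)

    @property
    def family_ids(self) -> list[str]:
        return [f.family_id for f in self.families]

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family(self, family_id: str) -> FamilyRecord:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def week_of(self, day: int) -> int:
        return day // 7

    @property
    def n_weeks(self) -> int:
        return (self.study_days + 6) // 7


def _check_pedigree_acyclic(entries: list[PedigreeEntry]) -> None:
    parents = {e.individual_id: (e.father_id, e.mother_id) for e in entries}
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if node not in parents:
            return
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            raise ValueError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
        state[node] = 0
        stack.append(node)
        for p in parents[node]:
            if p is not None:
                visit(p, stack)
        stack.pop()
        state[node] = 1

    for e in entries:
        visit(e.individual_id, [])


@dataclass(frozen=True)
class InterviewRecord:
    """One interview by one family, covering the two preceding days."""

    reporter_family: str
    interview_day: int
    covered_days: frozenset[int]
    # (role in {"host","guest"}, partner_family, event_day)
    reports: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        for role, partner, day in self.reports:
            if role not in ("host", "guest"):
                raise ValueError(f"unknown role {role!r}")
            if day not in self.covered_days:
                raise ValueError(
                    f"interview of {self.reporter_family} on day "
                    f"{self.interview_day}: reported event day {day} outside "
                    f"covered days {sorted(self.covered_days)}"
                )


def covered_days_for(interview_day: int, study_days: int | None = None) -> frozenset[int]:
    """Days covered by an interview: exactly the two preceding days."""
    days = {d for d in range(interview_day - RECALL_DAYS, interview_day) if d >= 0}
    if study_days is not None:
        days = {d for d in days if d < study_days}
    return frozenset(days)


@dataclass(frozen=True, order=True)
class Event:
    host: str
    guest: str
    day: int


@dataclass
class EventPanel:
    """Hosting / observability tensors over (host, guest, day).

    ``h[i, j, t] = 1`` iff family *i* was recorded hosting family *j* on day
    *t*; ``o[i, j, t] = 1`` iff that cell was potentially observable;
    ``guest_only[i, j, t] = 1`` iff it was covered only by the guest's
    interview (the under-reporting flag of the regression analysis).
    """

    family_ids: list[str]
    h: np.ndarray  # uint8 (F, F, T)
    o: np.ndarray
    guest_only: np.ndarray

    def __post_init__(self) -> None:
        F = len(self.family_ids)
        for name in ("h", "o", "guest_only"):
            a = getattr(self, name)
            if a.shape[:2] != (F, F):
                raise ValueError(f"{name} has shape {a.shape}, expected ({F},{F},T)")
            setattr(self, name, np.asarray(a, dtype=np.uint8))
        if np.any(self.h > self.o):
            raise ValueError("panel violates h <= o: an event on an unobservable cell")
        if np.any(self.guest_only > self.o):
            raise ValueError("guest_only cells must be observable")
        idx = np.arange(F)
        if self.h[idx, idx].any() or self.o[idx, idx].any():
            raise ValueError("diagonal (i hosts i) must be identically zero")

    @property
    def n_days(self) -> int:
        return self.h.shape[2]

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def risk_days(self) -> int:
        """Total number of host-guest risk days (sum of o)."""
        return int(self.o.sum())

    @property
    def n_events(self) -> int:
        return int(self.h.sum())

    def to_long(self) -> pd.DataFrame:
        """Tidy long export: one row per observable cell."""
        i, j, t = np.nonzero(self.o)
        return pd.DataFrame(
            {
                "host": np.asarray(self.family_ids)[i],
                "guest": np.asarray(self.family_ids)[j],
                "day": t,
                "h": self.h[i, j, t],
                "o": self.o[i, j, t],
                "guest_only": self.guest_only[i, j, t],
            }
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_village(families_path: str | Path, pedigree_path: str | Path,
                 study_days: int = 112) -> Village:
    """Read a village from a families CSV and a PED-like pedigree TSV.

    Unknown parent ids in the pedigree are treated as founders (with a
    warning); '0' or empty parent fields mean a missing (founder) parent.
    """
    fam_df = pd.read_csv(families_path, dtype=str)
    if fam_df.empty:
        raise ValueError(f"{families_path}: zero families listed")
    families = []
    for _, row in fam_df.iterrows():
        families.append(
            FamilyRecord(
                family_id=row["family_id"],
                member_ids=tuple(row["member_ids"].split(";")),
                head_ages=tuple(float(a) for a in row["head_ages"].split(";")),
                location=(float(row["lat"]), float(row["lon"])),
            )
        )
        declared = int(row["size"])
        if declared != families[-1].size:
            raise ValueError(
                f"family {row['family_id']}: declared size {declared} != "
                f"{families[-1].size} listed members"
            )

    ped_df = pd.read_csv(
        pedigree_path, sep="\t", dtype=str, header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex"],
    )
    known = set(ped_df["individual_id"])

    def _parent(x: str | float) -> str | None:
        if pd.isna(x) or x in ("0", ""):
            return None
        if x not in known:
            warnings.warn(
                f"pedigree references unknown parent {x!r}; treated as absent "
                "(founder convention)", stacklevel=2,
            )
            return None
        return str(x)

    individuals = [
        PedigreeEntry(
            individual_id=row["individual_id"],
            father_id=_parent(row["father_id"]),
            mother_id=_parent(row["mother_id"]),
            family_id=row["family_id"],
            sex=None if pd.isna(row["sex"]) else str(row["sex"]),
        )
        for _, row in ped_df.iterrows()
    ]
    return Village(families=families, individuals=individuals, study_days=study_days)


def write_village(village: Village, families_path: str | Path,
                  pedigree_path: str | Path) -> None:
    fam_rows = [
        {
            "family_id": f.family_id,
            "member_ids": ";".join(f.member_ids),
            "head_ages": ";".join(str(a) for a in f.head_ages),
            "size": f.size,
            "lat": f.location[0],
            "lon": f.location[1],
        }
        for f in village.families
    ]
    pd.DataFrame(fam_rows).to_csv(families_path, index=False)
    ped_rows = [
        {
            "family_id": p.family_id,
            "individual_id": p.individual_id,
            "father_id": p.father_id or "0",
            "mother_id": p.mother_id or "0",
            "sex": p.sex or "0",
        }
        for p in village.individuals
    ]
    pd.DataFrame(ped_rows).to_csv(pedigree_path, sep="\t", index=False, header=False)


def read_interviews(path: str | Path, village: Village) -> list[InterviewRecord]:
    """Read interview reports; one CSV row per reported event.

    Rows with an empty role/partner record an interview that reported no
    events (they still contribute observation coverage).
    """
    df = pd.read_csv(path, dtype={"reporter_family": str, "partner_family": str})
    if df.empty:
        return []
    fam_ids = set(village.family_ids)
    records: list[InterviewRecord] = []
    for (reporter, day), grp in df.groupby(["reporter_family", "interview_day"], sort=True):
        if reporter not in fam_ids:
            raise ValueError(f"unknown reporter family {reporter!r}")
        day = int(day)
        covered = covered_days_for(day, village.study_days)
        reports = []
        for rownum, row in grp.iterrows():
            if pd.isna(row.get("role")) or pd.isna(row.get("partner_family")) \
                    or str(row.get("role")) == "" :
                continue
            partner = str(row["partner_family"])
            if partner not in fam_ids:
                raise ValueError(f"row {rownum}: unknown partner family {partner!r}")
            event_day = int(row["event_day"])
            if event_day not in covered:
                raise ValueError(
                    f"row {rownum}: event day {event_day} outside days covered "
                    f"by the day-{day} interview of {reporter}"
                )
            reports.append((str(row["role"]), partner, event_day))
        records.append(
            InterviewRecord(
                reporter_family=str(reporter),
                interview_day=day,
                covered_days=covered,
                reports=tuple(sorted(reports)),
            )
        )
    records.sort(key=lambda r: (r.interview_day, r.reporter_family))
    return records


def write_interviews(records: list[InterviewRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if not rec.reports:
            rows.append(
                {"reporter_family": rec.reporter_family,
                 "interview_day": rec.interview_day,
                 "role": "", "partner_family": "", "event_day": ""}
            )
        for role, partner, day in rec.reports:
            rows.append(
                {"reporter_family": rec.reporter_family,
                 "interview_day": rec.interview_day,
                 "role": role, "partner_family": partner, "event_day": day}
            )
    pd.DataFrame(
        rows, columns=["reporter_family", "interview_day", "role",
                       "partner_family", "event_day"]
    ).to_csv(path, index=False)


def write_events(events: list[Event], path: str | Path) -> None:
    pd.DataFrame([{"host": e.host, "guest": e.guest, "day": e.day} for e in events],
                 columns=["host", "guest", "day"]).to_csv(path, index=False)


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, dtype={"host": str, "guest": str})
    return [Event(r.host, r.guest, int(r.day)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def reconcile_reports(records: list[InterviewRecord], seed: int = 0) -> list[Event]:
    """Merge host- and guest-side reports into a deduplicated event list.

    A dyad-day is an event if *either* party reported it (positive reports
    win, reflecting guest under-reporting).  When the host and the guest of
    the same pair report the same event under divergent dates (within a
    ``DIVERGENT_DATE_WINDOW``-day window, with no exactly matching
    counterpart report), exactly one of the two dates is kept, chosen
    uniformly at random under ``seed``.
    """
    host_claims: set[tuple[str, str, int]] = set()
    guest_claims: set[tuple[str, str, int]] = set()
    for rec in records:
        for role, partner, day in rec.reports:
            if role == "host":
                host_claims.add((rec.reporter_family, partner, day))
            else:
                guest_claims.add((partner, rec.reporter_family, day))

    matched = host_claims & guest_claims
    open_host = host_claims - matched
    open_guest = guest_claims - matched

    rng = np.random.default_rng(seed)
    events: set[tuple[str, str, int]] = set(matched)

    pairs = sorted({(h, g) for h, g, _ in open_host} | {(h, g) for h, g, _ in open_guest})
    for h, g in pairs:
        hd = sorted(d for hh, gg, d in open_host if (hh, gg) == (h, g))
        gd = sorted(d for hh, gg, d in open_guest if (hh, gg) == (h, g))
        used_g: set[int] = set()
        for d1 in hd:
            partner_day = None
            for d2 in gd:
                if d2 in used_g or d2 == d1:
                    continue
                if abs(d2 - d1) <= DIVERGENT_DATE_WINDOW:
                    partner_day = d2
                    break
            if partner_day is None:
                events.add((h, g, d1))
            else:
                used_g.add(partner_day)
                keep = d1 if rng.integers(2) == 0 else partner_day
                logger.debug("divergent dates %s->%s: host=%d guest=%d kept=%d",
                             h, g, d1, partner_day, keep)
                events.add((h, g, keep))
        for d2 in gd:
            if d2 not in used_g:
                events.add((h, g, d2))

    return sorted(Event(h, g, d) for h, g, d in events)


# ---------------------------------------------------------------------------
# Panel construction and summaries
# ---------------------------------------------------------------------------

def coverage_matrix(village: Village, records: list[InterviewRecord]) -> np.ndarray:
    """(F, T) boolean: family f's interviews covered day t."""
    F, T = village.n_families, village.study_days
    cov = np.zeros((F, T), dtype=bool)
    fam_index = {fid: k for k, fid in enumerate(village.family_ids)}
    for rec in records:
        fi = fam_index[rec.reporter_family]
        for d in rec.covered_days:
            if 0 <= d < T:
                cov[fi, d] = True
    return cov


def build_panel(village: Village, records: list[InterviewRecord],
                events: list[Event]) -> EventPanel:
    """Assemble the hosting/observability panel from coverage and events."""
    F, T = village.n_families, village.study_days
    cov = coverage_matrix(village, records)
    o = cov[:, None, :] | cov[None, :, :]
    guest_only = cov[None, :, :] & ~cov[:, None, :]
    idx = np.arange(F)
    o[idx, idx, :] = False
    guest_only[idx, idx, :] = False

    h = np.zeros((F, F, T), dtype=np.uint8)
    fam_index = {fid: k for k, fid in enumerate(village.family_ids)}
    for ev in events:
        i, j = fam_index[ev.host], fam_index[ev.guest]
        if i == j:
            raise ValueError(f"self-hosting event for family {ev.host}")
        if not o[i, j, ev.day]:
            raise ValueError(
                f"event ({ev.host} hosts {ev.guest}, day {ev.day}) on an "
                "uncovered dyad-day violates h <= o"
            )
        h[i, j, ev.day] = 1

    return EventPanel(
        family_ids=list(village.family_ids),
        h=h, o=o.astype(np.uint8), guest_only=guest_only.astype(np.uint8),
    )


def panel_summaries(panel: EventPanel) -> dict:
    """Windowing-corrected summary rates of the event panel.

    Rates are events per risk day at the relevant aggregation; units with
    zero risk days are reported as missing (NaN).
    """
    h, o = panel.h.astype(float), panel.o.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        host_events = h.sum(axis=(1, 2))
        host_risk = o.sum(axis=(1, 2))
        hosting_rate = np.where(host_risk > 0, host_events / host_risk, np.nan)
        guest_events = h.sum(axis=(0, 2))
        guest_risk = o.sum(axis=(0, 2))
        attendance_rate = np.where(guest_risk > 0, guest_events / guest_risk, np.nan)
        dyad_events = h.sum(axis=2)
        dyad_risk = o.sum(axis=2)
        dyad_rate = np.where(dyad_risk > 0, dyad_events / dyad_risk, np.nan)

    F = panel.n_families
    n_directed = F * (F - 1)
    per_family = pd.DataFrame(
        {
            "family_id": panel.family_ids,
            "hosting_rate": hosting_rate,
            "attendance_rate": attendance_rate,
        }
    )
    total_risk = panel.risk_days
    return {
        "n_events": panel.n_events,
        "risk_days": total_risk,
        "hosting_rate": panel.n_events / total_risk if total_risk else np.nan,
        "per_family": per_family,
        "var_hosting_rate": (
            float(np.nanvar(hosting_rate)) if np.isfinite(hosting_rate).any()
            else np.nan
        ),
        "var_attendance_rate": (
            float(np.nanvar(attendance_rate)) if np.isfinite(attendance_rate).any()
            else np.nan
        ),
        "dyad_rate": dyad_rate,
        "n_dyads_with_event": int((dyad_events > 0).sum()),
        "n_directed_dyads": n_directed,
        "frac_dyads_with_event": float((dyad_events > 0).sum() / n_directed),
    }
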