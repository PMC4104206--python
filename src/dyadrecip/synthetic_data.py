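"""Synthetic village and event-history generator with known ground truth.

The generator emulates the study system: a small horticulturalist village of
~35 nuclear families (~200 people, three-plus generations of pedigree,
kin-clustered household locations) observed for 16 weeks, where families
host drinking parties whose guests are drawn with kin-, distance- and
dyad-specific preferences.  An optional *conditional-action reciprocity
kernel* multiplies the weight of guest *j* for host *i* by ``rho`` whenever
*j* hosted *i* within the past ``w`` days (and boosts *i*'s party
probability), injecting a short-timescale reciprocity mechanism with known
strength.  With ``rho = 1`` the process is exactly i.i.d. across days given
the stationary preferences.

Observation is by an interview process: each family is interviewed roughly
twice a week about the two preceding days; hosts report their own parties
reliably, guests under-report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_model import (
    Event,
    FamilyRecord,
    InterviewRecord,
    PedigreeEntry,
    Village,
    covered_days_for,
)
from .kinship_space import (
    KIN_THRESHOLD,
    Pedigree,
    family_distances,
    family_relatedness,
    kin_class,
)

ALL_KIN_CLASSES = ("close_kin", "distant_kin", "non_kin")

#: weekly seasonal multipliers (16 weeks): an active early season, a lull,
#: then a second active period — normalized to mean 1 below
_SEASON_SHAPE = np.array(
    [1.4, 1.4, 1.3, 1.2, 1.0, 0.6, 0.5, 0.6, 1.1, 1.2, 1.2, 1.1, 1.0, 0.9, 0.9, 0.8]
)


def seasonal_multipliers(n_days: int) -> np.ndarray:
    """Per-day seasonal multiplier on the party probability (mean 1)."""
    weeks = np.arange(n_days) // 7
    shape = _SEASON_SHAPE[weeks % len(_SEASON_SHAPE)]
    return shape / shape.mean()


@dataclass
class SimParams:
    """Generative parameters of the synthetic study.

    Defaults are calibrated to the scale of the study system: ~0.9% daily
    hosting probability per directed dyad, ~2 guest families per party,
    two interviews per family-week and guest report probability 0.38.
    """

    n_families: int = 35
    n_days: int = 112
    base_host_rate: float = 0.30
    #: (linear, quadratic) log-rate coefficients on centered head age;
    #: peak near age 55
    age_effect: tuple[float, float] = (0.05, -0.0025)
    #: geometric success prob for party size (size = 1 + Geom failures)
    party_size_p: float = 0.5
    beta_dist: float = -1.2  # on log km
    beta_kin: float = 8.0  # on mean relatedness
    sigma_dyad: float = 1.0  # sd of lognormal dyad preference effects
    recip_strength: float = 1.0  # rho: hazard multiplier, 1 = no mechanism
    recip_window: int = 3  # w, days
    recip_classes: tuple[str, ...] = ALL_KIN_CLASSES
    recip_host_boost: float = 0.5  # share of (rho-1)*base added to party prob
    interview_rate: float = 2.0  # interviews / family / week
    guest_report_prob: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.base_host_rate <= 1:
            raise ValueError("base_host_rate must be a probability")
        if not 0 <= self.guest_report_prob <= 1:
            raise ValueError("guest_report_prob must be a probability")
        if self.recip_strength < 0:
            raise ValueError("recip_strength must be >= 0")
        if self.recip_window < 1:
            raise ValueError("recip_window must be >= 1")
        if not 0 < self.party_size_p <= 1:
            raise ValueError("party_size_p must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually did: stationary preferences and kernel."""

    family_ids: list[str]
    #: stationary per-day probability that i hosts j (rho = 1 margins)
    pref: np.ndarray
    rho: float
    window: int
    recip_classes: tuple[str, ...]
    seed: int
    true_events: list[Event] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "family_ids": self.family_ids,
            "pref": self.pref.tolist(),
            "rho": self.rho,
            "window": self.window,
            "recip_classes": list(self.recip_classes),
            "seed": self.seed,
            "true_events": [[e.host, e.guest, e.day] for e in self.true_events],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        p = json.loads(Path(path).read_text())
        return cls(
            family_ids=p["family_ids"],
            pref=np.asarray(p["pref"]),
            rho=p["rho"],
            window=p["window"],
            recip_classes=tuple(p["recip_classes"]),
            seed=p["seed"],
            true_events=[Event(h, g, d) for h, g, d in p["true_events"]],
        )


#: named substreams of the master seed (reproducible fixture generation)
_STREAMS = {"village": 1, "preferences": 2, "events": 3, "margins": 4, "interviews": 5}


def _substream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), tag])


# ---------------------------------------------------------------------------
# Village generation
# ---------------------------------------------------------------------------

#: demographic shape of the generated village: share of founder-generation
#: and middle-generation households, mean surplus fertility per generation,
#: village half-extent and household scatter around the natal compound (km)
_DEMOG = {
    "founder_frac": 0.25,
    "g1_frac": 0.40,
    "fert0": 3.5,
    "fert1": 3.5,
    "fert2": 3.0,
    "migrant_frac": 0.6,  # share of marriages to in-migrating spouses
    "extent_km": 2.5,
    "noise_km": 0.5,
}


def make_village(n_families: int, seed: int = 0, n_days: int = 112) -> Village:
    """Generate a village with >= 3 pedigree generations and kin-clustered
    household locations.

    Founder couples produce children who intermarry across founder lines;
    their children marry again, so the final village holds grandparent,
    parent and young-family households with full genealogical links.
    Households are placed near the husband's natal household, producing the
    kin-spatial confounding seen in real villages (relatedness explains
    roughly a fifth of the variance in log inter-household distance).
    """
    if n_families < 2:
        raise ValueError("need at least two families")
    rng = _substream(seed, 1)

    n0 = max(2, int(round(n_families * _DEMOG["founder_frac"])))
    m1 = max(0, int(round(n_families * _DEMOG["g1_frac"])))
    m2 = n_families - n0 - m1
    if m2 < 0:
        m1 += m2
        m2 = 0

    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"I{counter[0]:04d}"

    entries: list[PedigreeEntry] = []
    # founders
    g0_couples = []
    for _ in range(n0):
        husband, wife = new_id(), new_id()
        g0_couples.append((husband, wife))
        entries.append(PedigreeEntry(husband, None, None, family_id=""))
        entries.append(PedigreeEntry(wife, None, None, family_id=""))

    def have_children(couples, mean_children, lo=1):
        kids = []  # (child_id, father, mother, couple_index)
        for k, (f, m) in enumerate(couples):
            n_kids = lo + rng.poisson(mean_children)
            for _ in range(int(n_kids)):
                c = new_id()
                entries.append(PedigreeEntry(c, f, m, family_id=""))
                kids.append((c, f, m, k))
        return kids

    def marry(kids, n_couples):
        """Pair children across sibships or with in-migrating spouses."""
        pool = list(kids)
        rng.shuffle(pool)
        couples, used = [], set()
        for a in pool:
            if len(couples) >= n_couples:
                break
            if a[0] in used:
                continue
            if rng.random() < _DEMOG["migrant_frac"]:
                spouse = new_id()
                entries.append(PedigreeEntry(spouse, None, None, family_id=""))
                couples.append((a[0], spouse))
                used.add(a[0])
                continue
            for b in pool:
                if b[0] in used or b[0] == a[0] or b[3] == a[3]:
                    continue
                couples.append((a[0], b[0]))
                used.update((a[0], b[0]))
                break
        leftovers = [k for k in pool if k[0] not in used]
        return couples, leftovers

    g1_kids = have_children(g0_couples, _DEMOG["fert0"], lo=2)
    g1_couples, g1_home = marry(g1_kids, m1)
    g2_kids = have_children(g1_couples, _DEMOG["fert1"], lo=1)
    g2_couples, g2_home = marry(g2_kids, m2)
    g3_kids = have_children(g2_couples, _DEMOG["fert2"], lo=1)

    parent_couple_of: dict[str, int] = {}  # child -> index of natal family
    families_members: list[list[str]] = []
    families_ages: list[tuple[float, float]] = []
    couple_gen: list[int] = []

    def add_family(couple, age_lo, age_hi, gen):
        a1 = float(rng.uniform(age_lo, age_hi))
        a2 = float(np.clip(a1 + rng.normal(0, 3), 18, 80))
        families_members.append(list(couple))
        families_ages.append((a1, a2))
        couple_gen.append(gen)
        return len(families_members) - 1

    g0_index = [add_family(c, 58, 75, 0) for c in g0_couples]
    g1_index = [add_family(c, 36, 57, 1) for c in g1_couples]
    g2_index = [add_family(c, 18, 35, 2) for c in g2_couples]

    husband_of_family = {idx: g0_couples[k][0] for k, idx in enumerate(g0_index)}
    husband_of_family.update({idx: g1_couples[k][0] for k, idx in enumerate(g1_index)})
    husband_of_family.update({idx: g2_couples[k][0] for k, idx in enumerate(g2_index)})

    # unmarried children live in their natal household
    couple_family = {}
    for k, idx in enumerate(g0_index):
        couple_family[("g0", k)] = idx
    for k, idx in enumerate(g1_index):
        couple_family[("g1", k)] = idx
    for c, f, m, k in g1_home:
        families_members[couple_family[("g0", k)]].append(c)
    for c, f, m, k in g2_home:
        families_members[couple_family[("g1", k)]].append(c)
    for c, f, m, k in g3_kids:
        families_members[g2_index[k]].append(c)

    # cap family size at 10 by moving surplus children to the smallest family
    for members in families_members:
        while len(members) > 10:
            surplus = members.pop()
            smallest = min(families_members, key=len)
            smallest.append(surplus)

    natal_center: dict[str, int] = {}
    for c, f, m, k in g1_kids:
        natal_center[c] = g0_index[k]
    for c, f, m, k in g2_kids:
        natal_center[c] = g1_index[k]

    # kin-clustered spatial layout: founder compounds in a ~2 km village,
    # each descendant household near the husband's natal household
    base_lat, base_lon = -14.90, -66.90
    lat_scale = 1.0 / 111.19  # degrees per km
    extent = _DEMOG["extent_km"]
    centers = {}
    for idx in g0_index:
        centers[idx] = (
            base_lat + rng.uniform(-extent, extent) * lat_scale,
            base_lon + rng.uniform(-extent, extent) * lat_scale,
        )
    locations: list[tuple[float, float]] = [None] * len(families_members)
    for idx in g0_index:
        locations[idx] = centers[idx]
    noise_km = _DEMOG["noise_km"]
    for order in (g1_index, g2_index):
        for idx in order:
            husband = husband_of_family[idx]
            parent_idx = natal_center.get(husband)
            if parent_idx is None or locations[parent_idx] is None:
                anchor = (base_lat, base_lon)
            else:
                anchor = locations[parent_idx]
            locations[idx] = (
                float(anchor[0] + rng.normal(0, noise_km) * lat_scale),
                float(anchor[1] + rng.normal(0, noise_km) * lat_scale),
            )

    member_family: dict[str, str] = {}
    fam_records = []
    for k, members in enumerate(families_members):
        fid = f"F{k + 1:02d}"
        for m in members:
            member_family[m] = fid
        fam_records.append(
            FamilyRecord(
                family_id=fid,
                member_ids=tuple(members),
                head_ages=families_ages[k],
                location=locations[k],
            )
        )
    entries = [
        PedigreeEntry(e.individual_id, e.father_id, e.mother_id,
                      family_id=member_family.get(e.individual_id, ""))
        for e in entries
    ]
    # every individual must belong to exactly one family
    assert all(e.family_id for e in entries)
    return Village(families=fam_records, individuals=entries, study_days=n_days)


# ---------------------------------------------------------------------------
# Event simulation
# ---------------------------------------------------------------------------

def _age_multiplier(ages: np.ndarray, age_effect: tuple[float, float]) -> np.ndarray:
    b1, b2 = age_effect
    x = ages - 45.0
    return np.exp(b1 * x + b2 * x**2)


def stationary_preferences(village: Village, params: SimParams,
                           rng: np.random.Generator | None = None):
    """Per-day party probabilities and guest-selection weights.

    Returns (party_prob per family, weight matrix W[i, j], kin-class matrix).
    """
    if rng is None:
        rng = _substream(params.seed, 2)
    F = village.n_families
    ages = np.array([f.head_age for f in village.families])
    party_prob = np.clip(
        params.base_host_rate * _age_multiplier(ages, params.age_effect), 0, 1
    )
    relmat = family_relatedness(Pedigree(village.individuals), village)
    distmat = family_distances(village)
    d = np.maximum(distmat.d, 0.05)  # floor at 50 m for the log
    eps = rng.normal(0, params.sigma_dyad, size=(F, F))
    W = np.exp(params.beta_dist * np.log(d) + params.beta_kin * relmat.r + eps)
    np.fill_diagonal(W, 0.0)
    classes = np.empty((F, F), dtype=object)
    for i in range(F):
        for j in range(F):
            classes[i, j] = kin_class(min(relmat.r[i, j], 1.0)) if i != j else ""
    return party_prob, W, classes


def _mean_inclusion_prob(W: np.ndarray, size_p: float, n_mc: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo inclusion probability of each guest given a party."""
    F = W.shape[0]
    incl = np.zeros_like(W)
    for i in range(F):
        w = W[i].copy()
        others = np.flatnonzero(w > 0)
        if others.size == 0:
            continue
        logw = np.log(w[others])
        for _ in range(n_mc):
            k = min(1 + rng.geometric(size_p) - 1, others.size)
            g = rng.gumbel(size=others.size)
            chosen = others[np.argsort(-(logw + g))[:k]]
            incl[i, chosen] += 1.0
    return incl / n_mc


def simulate_events(village: Village, params: SimParams
                    ) -> tuple[GroundTruth, list[Event]]:
    """Simulate the day-by-day hosting process.

    Each day, family *i* throws a party with probability
    ``party_prob_i x seasonal multiplier`` (plus a reciprocity boost when the
    kernel is active and someone in an eligible kin class hosted *i* within
    the window); the guest count is geometric; guests are drawn without
    replacement with weights ``W[i, j]``, multiplied by ``rho`` for eligible
    recent hosts of *i*.
    """
    rng = _substream(params.seed, 3)
    F, T = village.n_families, params.n_days
    party_prob, W, classes = stationary_preferences(village, params, rng)
    season = seasonal_multipliers(T)
    rho, w = params.recip_strength, params.recip_window

    eligible = np.zeros((F, F), dtype=bool)
    for i in range(F):
        for j in range(F):
            if i != j and classes[i, j] in params.recip_classes:
                eligible[i, j] = True

    h = np.zeros((F, F, T), dtype=np.uint8)
    events: list[Event] = []
    fam_ids = village.family_ids
    boost = params.recip_host_boost * (rho - 1.0) * params.base_host_rate

    for t in range(T):
        lo = max(0, t - w)
        recent = h[:, :, lo:t].any(axis=2) if t > 0 else np.zeros((F, F), bool)
        # recent[j, i] True: j hosted i within the window
        for i in range(F):
            p = party_prob[i] * season[t]
            owed = eligible[i] & recent[:, i]  # j hosted i recently, class eligible
            if rho != 1.0 and owed.any():
                p = p + boost
            if rng.random() >= min(p, 1.0):
                continue
            weights = W[i].copy()
            if rho != 1.0:
                weights[owed] *= rho
            positive = np.flatnonzero(weights > 0)
            if positive.size == 0:
                continue
            k = min(1 + rng.geometric(params.party_size_p) - 1, positive.size)
            if k >= F:
                raise ValueError("party size must be smaller than the village")
            g = rng.gumbel(size=positive.size)
            chosen = positive[np.argsort(-(np.log(weights[positive]) + g))[:k]]
            for j in chosen:
                h[i, j, t] = 1
                events.append(Event(fam_ids[i], fam_ids[j], t))

    # stationary margins for ground truth: P(i hosts j) under rho = 1
    incl = _mean_inclusion_prob(W, params.party_size_p, n_mc=400,
                                rng=_substream(params.seed, 4))
    pref = party_prob[:, None] * incl
    np.fill_diagonal(pref, 0.0)
    gt = GroundTruth(
        family_ids=list(fam_ids), pref=pref, rho=rho, window=w,
        recip_classes=params.recip_classes, seed=params.seed, true_events=events,
    )
    return gt, events


# ---------------------------------------------------------------------------
# Interview observer
# ---------------------------------------------------------------------------

def simulate_interviews(events: list[Event], village: Village,
                        params: SimParams) -> list[InterviewRecord]:
    """Observe true events through the twice-weekly interview process.

    Hosts report their own parties with probability 1; guests report events
    they attended with probability ``guest_report_prob``.
    """
    rng = _substream(params.seed, 5)
    F, T = village.n_families, params.n_days
    hosted: dict[tuple[str, int], list[str]] = {}
    attended: dict[tuple[str, int], list[str]] = {}
    # under-reporting is a per-event disposition: a guest either discloses an
    # attended event (in every interview covering it) or never mentions it
    guest_discloses = rng.random(len(events)) < params.guest_report_prob
    for ev, disclosed in zip(events, guest_discloses):
        hosted.setdefault((ev.host, ev.day), []).append(ev.guest)
        if disclosed:
            attended.setdefault((ev.guest, ev.day), []).append(ev.host)

    records: list[InterviewRecord] = []
    n_weeks = (T + 6) // 7
    for fam in village.family_ids:
        for week in range(n_weeks):
            n_int = int(params.interview_rate)
            if rng.random() < params.interview_rate - n_int:
                n_int += 1
            week_days = np.arange(week * 7, min((week + 1) * 7, T))
            if week_days.size == 0 or n_int == 0:
                continue
            days = rng.choice(week_days, size=min(n_int, week_days.size),
                              replace=False)
            for day in sorted(int(d) for d in days):
                covered = covered_days_for(day, T)
                reports = []
                for d in sorted(covered):
                    for guest in hosted.get((fam, d), []):
                        reports.append(("host", guest, d))
                    for host in attended.get((fam, d), []):
                        reports.append(("guest", host, d))
                records.append(
                    InterviewRecord(
                        reporter_family=fam, interview_day=day,
                        covered_days=covered, reports=tuple(reports),
                    )
                )
    records.sort(key=lambda r: (r.interview_day, r.reporter_family))
    return records


def simulate_study(params: SimParams
                   ) -> tuple[Village, GroundTruth, list[Event], list[InterviewRecord]]:
    """Convenience: village + events + interviews under one parameter set."""
    village = make_village(params.n_families, seed=params.seed, n_days=params.n_days)
    gt, events = simulate_events(village, params)
    records = simulate_interviews(events, village, params)
    return village, gt, events, records
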