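"""Trophic-role inference from post-emergence mummy DNA-detection tables.

A mummy record states which parasitoid emerged from it and which target DNAs
(psyllid plus each parasitoid morphospecies) were PCR-detectable afterwards.
Records are informative only when both psyllid DNA and the emerged species'
own DNA were detected; informative records drive the classification:

* an emerged species whose mummies consistently contain no other parasitoid
  DNA is a primary parasitoid of the psyllid;
* an emerged species whose mummies consistently contain exactly one other
  parasitoid species X, and which never appears alone, is a hyperparasitoid
  of X;
* a morphospecies whose females classify primary while its males classify
  hyperparasitoid is a heteronomous hyperparasitoid with per-sex prey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError, SchemaError

PSYLLID = "psyllid"

PRIMARY = "primary"
HYPERPARASITOID = "hyperparasitoid"
HETERONOMOUS = "heteronomous_hyperparasitoid"
UNDETERMINED = "undetermined"

_REQUIRED_COLUMNS = (
    "mummy_id",
    "host_species",
    "emerged_species",
    "emerged_sex",
    "psyllid_dna",
)
_TRUE = {"1", "yes", "true", "y"}
_FALSE = {"0", "no", "false", "n"}


@dataclass
class MummyRecord:
    mummy_id: str
    host_species: str
    emerged_species: str
    emerged_sex: str
    psyllid_dna: bool
    detected: dict[str, bool]

    def __post_init__(self) -> None:
        if self.emerged_species not in self.detected:
            raise InputError(
                f"mummy {self.mummy_id!r}: detection map lacks the emerged "
                f"species {self.emerged_species!r}"
            )

    def other_species(self) -> set[str]:
        """Non-emerged parasitoid species whose DNA was detected."""
        return {
            t for t, v in self.detected.items() if v and t != self.emerged_species
        }


def _parse_bool(value, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise InputError(f"cannot parse boolean {value!r} in column {column!r}")


def load_mummy_table(path: str | Path) -> list[MummyRecord]:
    """Read the mummy CSV schema (``det_<TARGET>`` columns hold the panel)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mummy table missing required columns: {missing}")
    det_cols = [c for c in df.columns if c.startswith("det_")]
    if not det_cols:
        raise SchemaError("mummy table has no det_<TARGET> columns")
    records = []
    seen = set()
    for _, row in df.iterrows():
        mid = str(row["mummy_id"])
        if mid in seen:
            raise InputError(f"duplicate mummy_id {mid!r}")
        seen.add(mid)
        records.append(
            MummyRecord(
                mummy_id=mid,
                host_species=str(row["host_species"]),
                emerged_species=str(row["emerged_species"]),
                emerged_sex=str(row["emerged_sex"]),
                psyllid_dna=_parse_bool(row["psyllid_dna"], "psyllid_dna"),
                detected={
                    c[len("det_") :]: _parse_bool(row[c], c) for c in det_cols
                },
            )
        )
    return records


def write_mummy_table(records: list[MummyRecord], path: str | Path) -> None:
    targets = sorted({t for r in records for t in r.detected})
    rows = []
    for r in records:
        row = {
            "mummy_id": r.mummy_id,
            "host_species": r.host_species,
            "emerged_species": r.emerged_species,
            "emerged_sex": r.emerged_sex,
            "psyllid_dna": int(r.psyllid_dna),
        }
        for t in targets:
            row[f"det_{t}"] = int(r.detected.get(t, False))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def flag_informative(
    records: list[MummyRecord],
) -> tuple[list[MummyRecord], list[MummyRecord]]:
    """Informative iff psyllid DNA and the emerged species' DNA were detected."""
    informative, uninformative = [], []
    for r in records:
        if r.psyllid_dna and r.detected[r.emerged_species]:
            informative.append(r)
        else:
            uninformative.append(r)
    return informative, uninformative


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def detection_success(
    records: list[MummyRecord],
    by: tuple[str, ...] = ("host_species", "emerged_species", "emerged_sex"),
) -> pd.DataFrame:
    """Percent informative mummies per stratum, rounded half-up to integers."""
    informative, _ = flag_informative(records)
    informative_ids = {r.mummy_id for r in informative}
    strata: dict[tuple, list[bool]] = {}
    for r in records:
        key = tuple(getattr(r, f) for f in by)
        strata.setdefault(key, []).append(r.mummy_id in informative_ids)
    rows = []
    for key in sorted(strata):
        flags = strata[key]
        n_inf = sum(flags)
        rows.append(
            dict(zip(by, key))
            | {
                "informative": n_inf,
                "uninformative": len(flags) - n_inf,
                "detection_success": _round_half_up(100.0 * n_inf / len(flags)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrophicAssignment:
    host_species: str
    morphospecies: str
    sex_scope: str  # "female" | "male" | "both"
    role: str
    prey: str | None = None
    prey_by_sex: dict[str, str] | None = None
    support: tuple[int, int] = (0, 0)  # (conforming, contradicting)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role == PRIMARY and self.prey not in (PSYLLID, None):
            raise InputError("primary role requires psyllid prey")
        if self.role == HYPERPARASITOID and self.prey in (PSYLLID, None):
            raise InputError("hyperparasitoid role requires a parasitoid prey")


def _classify_stratum(
    records: list[MummyRecord], consistency: float, min_n: int
) -> tuple[str, str | None, tuple[int, int], list[str]]:
    n = len(records)
    if n < min_n:
        return UNDETERMINED, None, (0, n), [f"only {n} informative mummies"]
    others = [r.other_species() for r in records]
    n_alone = sum(1 for o in others if not o)
    if n_alone / n >= consistency:
        return PRIMARY, PSYLLID, (n_alone, n - n_alone), []
    candidates = sorted({x for o in others for x in o})
    for x in candidates:
        n_exact = sum(1 for o in others if o == {x})
        if n_exact / n >= consistency and n_alone == 0:
            return HYPERPARASITOID, x, (n_exact, n - n_exact), []
    return (
        UNDETERMINED,
        None,
        (0, n),
        [
            "no consistent pattern: "
            f"{n_alone}/{n} alone, other-species sets {sorted(map(sorted, others))}"
        ],
    )


def classify_trophic_roles(
    records: list[MummyRecord],
    consistency: float = 1.0,
    min_n: int = 2,
) -> list[TrophicAssignment]:
    """Per (host, morphospecies) trophic assignments from informative mummies.

    Classification runs per sex first; a female-primary/male-hyperparasitoid
    morphospecies is re-labelled heteronomous with per-sex prey.  Small or
    inconsistent strata yield UNDETERMINED, never an exception.
    """
    if not (0.5 < consistency <= 1.0):
        raise InputError("consistency must lie in (0.5, 1.0]")
    informative, _ = flag_informative(records)
    strata: dict[tuple[str, str, str], list[MummyRecord]] = {}
    for r in informative:
        strata.setdefault(
            (r.host_species, r.emerged_species, r.emerged_sex), []
        ).append(r)

    by_host_species: dict[tuple[str, str], dict[str, tuple]] = {}
    for (host, sp, sex), recs in strata.items():
        by_host_species.setdefault((host, sp), {})[sex] = _classify_stratum(
            recs, consistency, min_n
        )

    assignments = []
    for (host, sp), by_sex in sorted(by_host_species.items()):
        f = by_sex.get("female")
        m = by_sex.get("male")
        if (
            f is not None
            and m is not None
            and f[0] == PRIMARY
            and m[0] == HYPERPARASITOID
        ):
            assignments.append(
                TrophicAssignment(
                    host_species=host,
                    morphospecies=sp,
                    sex_scope="both",
                    role=HETERONOMOUS,
                    prey_by_sex={"female": PSYLLID, "male": m[1]},
                    support=(f[2][0] + m[2][0], f[2][1] + m[2][1]),
                    notes=f[3] + m[3],
                )
            )
            continue
        if f is not None and m is not None and f[0] == m[0] and f[1] == m[1]:
            assignments.append(
                TrophicAssignment(
                    host_species=host,
                    morphospecies=sp,
                    sex_scope="both",
                    role=f[0],
                    prey=f[1],
                    support=(f[2][0] + m[2][0], f[2][1] + m[2][1]),
                    notes=f[3] + m[3],
                )
            )
            continue
        for sex, res in sorted(by_sex.items()):
            assignments.append(
                TrophicAssignment(
                    host_species=host,
                    morphospecies=sp,
                    sex_scope=sex,
                    role=res[0],
                    prey=res[1],
                    support=res[2],
                    notes=res[3],
                )
            )
    return assignments


def validate_prey_consistency(
    assignments: list[TrophicAssignment],
) -> list[str]:
    """Hyperparasitoid prey should classify primary in the same host system.

    Violations are reported as warnings, never raised.
    """
    warnings = []
    roles: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        roles.setdefault((a.host_species, a.morphospecies), set()).add(a.role)
    for a in assignments:
        preys = []
        if a.role == HYPERPARASITOID and a.prey:
            preys.append(a.prey)
        if a.role == HETERONOMOUS and a.prey_by_sex:
            preys.extend(p for p in a.prey_by_sex.values() if p != PSYLLID)
        for prey in preys:
            prey_roles = roles.get((a.host_species, prey))
            if prey_roles is None:
                continue  # no data for the prey in this host system
            if PRIMARY not in prey_roles and prey_roles != {UNDETERMINED}:
                warnings.append(
                    f"{a.morphospecies} in {a.host_species} preys on {prey}, "
                    f"but {prey} classifies {sorted(prey_roles)} there"
                )
    return warnings


def summarize_species_roles(
    assignments: list[TrophicAssignment],
) -> dict[str, str]:
    """Collapse per-host assignments into one role call per morphospecies.

    A species called heteronomous in any host system stays heteronomous
    (female-only host systems only ever see its primary side); otherwise
    unanimity among determined host-level calls is required.
    """
    per_species: dict[str, list[TrophicAssignment]] = {}
    for a in assignments:
        per_species.setdefault(a.morphospecies, []).append(a)
    summary = {}
    for sp, calls in sorted(per_species.items()):
        roles = {c.role for c in calls if c.role != UNDETERMINED}
        if HETERONOMOUS in roles:
            female_side_ok = all(
                c.role in (HETERONOMOUS, PRIMARY)
                for c in calls
                if c.role != UNDETERMINED and c.sex_scope in ("female", "both")
            )
            male_side_ok = all(
                c.role in (HETERONOMOUS, HYPERPARASITOID)
                for c in calls
                if c.role != UNDETERMINED and c.sex_scope == "male"
            )
            summary[sp] = HETERONOMOUS if female_side_ok and male_side_ok else UNDETERMINED
        elif len(roles) == 1:
            summary[sp] = roles.pop()
        else:
            summary[sp] = UNDETERMINED
    return summary


def cooccurrence_check(
    records: list[MummyRecord], pair: tuple[str, str]
) -> int:
    """Count mummies whose detection map contains both species of ``pair``."""
    a, b = pair
    panel = {t for r in records for t in r.detected}
    for label in pair:
        if label not in panel:
            raise InputError(f"{label!r} is not a panel target")
    return sum(
        1 for r in records if r.detected.get(a, False) and r.detected.get(b, False)
    )


def assignments_to_frame(assignments: list[TrophicAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "host_species": a.host_species,
                "morphospecies": a.morphospecies,
                "sex_scope": a.sex_scope,
                "role": a.role,
                "prey": a.prey
                if a.prey_by_sex is None
                else ";".join(f"{s}:{p}" for s, p in sorted(a.prey_by_sex.items())),
                "n_conforming": a.support[0],
                "n_contradicting": a.support[1],
                "notes": "; ".join(a.notes),
            }
        )
    return pd.DataFrame(rows)
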