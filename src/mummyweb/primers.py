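"""Morphospecies-specific multiplex PCR primer design and in-silico validation.

Primers anchor on diagnostic alignment columns: positions where every target
sequence carries one fixed base that no non-target sequence carries.  A valid
pair has at least two diagnostic sites inside each primer's five 3'-terminal
positions, an amplicon of 145-400 bp, and near-equal Wallace-rule melting
temperatures.  Panels are split into the minimum number of multiplex stages
so that amplicon lengths stay distinguishable on a gel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError
from .seqdiv import AlignedSeqSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
PENTAMER = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def melting_temperature(primer: str) -> float:
    """Wallace rule: Tm = 2(A+T) + 4(G+C) degrees C."""
    if len(primer) < 8:
        raise InputError("primer too short for a Tm estimate (< 8 nt)")
    bad = set(primer) - set("ACGT")
    if bad:
        raise InputError(f"ambiguous bases in primer: {sorted(bad)}")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


@dataclass
class PrimerConstraints:
    primer_min: int = 16
    primer_max: int = 30
    amplicon_min: int = 145
    amplicon_max: int = 400
    tm_pair_tolerance: float = 2.0
    tm_window: float = 4.0
    length_separation: int = 30
    allowed_mismatches: int = 2
    min_diag_3prime: int = 2


@dataclass
class PrimerPair:
    """A species-specific pair in alignment coordinates (0-based half-open).

    ``forward`` is the template strand slice; ``reverse`` is given 5'->3' on
    the reverse strand (reverse complement of the template slice ending at
    ``rev_end``).
    """

    target: str
    forward: str
    reverse: str
    fwd_start: int
    rev_end: int
    tm_forward: float
    tm_reverse: float
    diagnostic_sites_3prime: tuple[int, int]

    @property
    def amplicon_length(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def fwd_end(self) -> int:
        return self.fwd_start + len(self.forward)

    @property
    def rev_start(self) -> int:
        return self.rev_end - len(self.reverse)


@dataclass
class NoSolutionReport:
    """Why no primer pair satisfying the constraints exists for a target."""

    target: str
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthiness signals "no solution"
        return False


@dataclass
class PrimerPanel:
    """One multiplex stage: co-amplifiable pairs with separable amplicons."""

    pairs: list[PrimerPair]
    annealing_temp: float
    length_separation: int

    def __post_init__(self) -> None:
        lengths = [p.amplicon_length for p in self.pairs]
        for a, b in itertools.combinations(lengths, 2):
            if abs(a - b) < self.length_separation:
                raise InputError(
                    f"amplicon lengths {a} and {b} closer than "
                    f"{self.length_separation} bp"
                )


def find_diagnostic_sites(
    target_seqs: AlignedSeqSet, other_seqs: AlignedSeqSet
) -> list[int]:
    """Columns fixed in the target and absent from every non-target sequence."""
    if target_seqs.length != other_seqs.length:
        raise InputError("target and non-target alignments differ in length")
    sites = []
    for pos in range(target_seqs.length):
        tbases = {r.residues[pos] for r in target_seqs}
        if len(tbases) != 1:
            continue
        base = next(iter(tbases))
        if base not in "ACGT":
            continue
        if all(r.residues[pos] != base for r in other_seqs):
            sites.append(pos)
    return sites


def _monomorphic_consensus(target_seqs: AlignedSeqSet) -> list[str | None]:
    """Per-column consensus base, or None where the target is polymorphic/gapped."""
    cons: list[str | None] = []
    for pos in range(target_seqs.length):
        bases = {r.residues[pos] for r in target_seqs}
        b = next(iter(bases)) if len(bases) == 1 else None
        cons.append(b if b in ("A", "C", "G", "T") else None)
    return cons


def design_species_primer(
    target: str,
    seqs: AlignedSeqSet,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | NoSolutionReport:
    """First valid pair in deterministic scan order.

    Scan order: leftmost forward start, then shortest amplicon, then shortest
    forward and reverse primer.  Primer windows must be target-monomorphic
    with no gaps, and each primer needs >= 2 diagnostic sites among its five
    3'-terminal alignment columns.
    """
    c = constraints or PrimerConstraints()
    targets = seqs.subset(morphospecies=target)
    others_records = [r for r in seqs if r.morphospecies != target]
    if not others_records:
        raise InputError("no non-target sequences to discriminate against")
    others = AlignedSeqSet(locus=seqs.locus, records=others_records)
    L = seqs.length
    if L < c.amplicon_min:
        raise InputError(
            f"alignment length {L} is shorter than the minimum amplicon "
            f"({c.amplicon_min} bp)"
        )
    diag = set(find_diagnostic_sites(targets, others))
    if not diag:
        return NoSolutionReport(
            target=target, reasons=["no diagnostic sites in alignment"]
        )
    cons = _monomorphic_consensus(targets)

    # candidate forward primers keyed by start, reverse primers keyed by end
    def window_ok(start: int, end: int) -> bool:
        return all(cons[i] is not None for i in range(start, end))

    def n_diag(start: int, end: int) -> int:
        return sum(1 for i in range(start, end) if i in diag)

    fwd_by_start: dict[int, list[tuple[int, str, float]]] = {}
    rev_by_end: dict[int, list[tuple[int, str, float]]] = {}
    for start in range(L - c.primer_min + 1):
        for ln in range(c.primer_min, c.primer_max + 1):
            end = start + ln
            if end > L or not window_ok(start, end):
                break  # a bad column blocks all longer windows too
            if n_diag(end - PENTAMER, end) >= c.min_diag_3prime:
                primer = "".join(cons[start:end])  # type: ignore[arg-type]
                fwd_by_start.setdefault(start, []).append(
                    (ln, primer, melting_temperature(primer))
                )
    for end in range(c.primer_min, L + 1):
        for ln in range(c.primer_min, c.primer_max + 1):
            start = end - ln
            if start < 0 or not window_ok(start, end):
                break
            if n_diag(start, start + PENTAMER) >= c.min_diag_3prime:
                template = "".join(cons[start:end])  # type: ignore[arg-type]
                primer = reverse_complement(template)
                rev_by_end.setdefault(end, []).append(
                    (ln, primer, melting_temperature(primer))
                )

    if not fwd_by_start or not rev_by_end:
        return NoSolutionReport(
            target=target,
            reasons=[
                "no forward primer window with >= "
                f"{c.min_diag_3prime} 3' diagnostic sites"
                if not fwd_by_start
                else "no reverse primer window with >= "
                f"{c.min_diag_3prime} 3' diagnostic sites"
            ],
        )

    saw_tm_failure = False
    for fwd_start in sorted(fwd_by_start):
        lo = fwd_start + c.amplicon_min
        hi = min(fwd_start + c.amplicon_max, L)
        for rev_end in range(lo, hi + 1):
            if rev_end not in rev_by_end:
                continue
            for fwd_len, fwd, tm_f in fwd_by_start[fwd_start]:
                for rev_len, rev, tm_r in rev_by_end[rev_end]:
                    if abs(tm_f - tm_r) > c.tm_pair_tolerance:
                        saw_tm_failure = True
                        continue
                    return PrimerPair(
                        target=target,
                        forward=fwd,
                        reverse=rev,
                        fwd_start=fwd_start,
                        rev_end=rev_end,
                        tm_forward=tm_f,
                        tm_reverse=tm_r,
                        diagnostic_sites_3prime=(
                            n_diag(fwd_start + fwd_len - PENTAMER, fwd_start + fwd_len),
                            n_diag(rev_end - rev_len, rev_end - rev_len + PENTAMER),
                        ),
                    )
    reasons = ["no forward/reverse combination yields a 145-400 bp amplicon"]
    if saw_tm_failure:
        reasons.append("some combinations failed only the Tm pair tolerance")
    return NoSolutionReport(target=target, reasons=reasons)


def check_primer_pair(
    pair: PrimerPair,
    seqs: AlignedSeqSet,
    constraints: PrimerConstraints | None = None,
) -> list[str]:
    """Independent constraint checker; returns a list of violations (empty = valid).

    Recomputes everything from the raw alignment without reusing the
    designer's candidate tables.
    """
    c = constraints or PrimerConstraints()
    violations: list[str] = []
    if not (c.primer_min <= len(pair.forward) <= c.primer_max):
        violations.append(f"forward primer length {len(pair.forward)} out of range")
    if not (c.primer_min <= len(pair.reverse) <= c.primer_max):
        violations.append(f"reverse primer length {len(pair.reverse)} out of range")
    if not (c.amplicon_min <= pair.amplicon_length <= c.amplicon_max):
        violations.append(f"amplicon length {pair.amplicon_length} out of range")
    if abs(pair.tm_forward - pair.tm_reverse) > c.tm_pair_tolerance:
        violations.append("Tm difference exceeds pair tolerance")
    try:
        if melting_temperature(pair.forward) != pair.tm_forward:
            violations.append("forward Tm does not match the Wallace rule")
        if melting_temperature(pair.reverse) != pair.tm_reverse:
            violations.append("reverse Tm does not match the Wallace rule")
    except InputError as exc:
        violations.append(str(exc))
        return violations

    target_rows = [r.residues for r in seqs if r.morphospecies == pair.target]
    other_rows = [r.residues for r in seqs if r.morphospecies != pair.target]
    if not target_rows or not other_rows:
        violations.append("alignment lacks target or non-target sequences")
        return violations

    def diagnostic(col: int) -> bool:
        bases = {row[col] for row in target_rows}
        if len(bases) != 1:
            return False
        b = next(iter(bases))
        return b in "ACGT" and all(row[col] != b for row in other_rows)

    # primers must match every target sequence exactly over their windows
    fwd_cols = range(pair.fwd_start, pair.fwd_start + len(pair.forward))
    rev_cols = range(pair.rev_end - len(pair.reverse), pair.rev_end)
    rev_template = reverse_complement(pair.reverse)
    for row in target_rows:
        if "".join(row[i] for i in fwd_cols) != pair.forward:
            violations.append("forward primer mismatches a target sequence")
            break
    for row in target_rows:
        if "".join(row[i] for i in rev_cols) != rev_template:
            violations.append("reverse primer mismatches a target sequence")
            break

    fwd_3prime = list(fwd_cols)[-PENTAMER:]
    rev_3prime = list(rev_cols)[:PENTAMER]
    if sum(diagnostic(i) for i in fwd_3prime) < c.min_diag_3prime:
        violations.append("forward primer lacks 2 diagnostic sites in 3' pentamer")
    if sum(diagnostic(i) for i in rev_3prime) < c.min_diag_3prime:
        violations.append("reverse primer lacks 2 diagnostic sites in 3' pentamer")
    return violations


def _stage_compatible(
    pairs: list[PrimerPair], length_separation: int, tm_window: float
) -> bool:
    lengths = [p.amplicon_length for p in pairs]
    for a, b in itertools.combinations(lengths, 2):
        if abs(a - b) < length_separation:
            return False
    tms = [t for p in pairs for t in (p.tm_forward, p.tm_reverse)]
    return (max(tms) - min(tms)) <= tm_window


def assemble_multiplex(
    pairs: list[PrimerPair],
    length_separation: int = 30,
    tm_window: float = 4.0,
) -> list[PrimerPanel]:
    """Partition pairs into the minimum number of co-amplifiable stages.

    Exact search over stage assignments (inputs are panel-sized, <= ~10
    pairs); ties broken deterministically by input order of the pairs.
    """
    if not pairs:
        raise InputError("no primer pairs to assemble")
    if len(pairs) > 12:
        raise InputError("multiplex assembly supports at most 12 pairs")
    n = len(pairs)
    for k in range(1, n + 1):
        # canonical assignments: pair i may only open stage max(used)+1
        def search(i: int, stages: list[list[int]]) -> list[list[int]] | None:
            if i == n:
                return [list(s) for s in stages]
            for s in stages:
                cand = [pairs[j] for j in s] + [pairs[i]]
                if _stage_compatible(cand, length_separation, tm_window):
                    s.append(i)
                    found = search(i + 1, stages)
                    if found is not None:
                        return found
                    s.pop()
            if len(stages) < k:
                stages.append([i])
                found = search(i + 1, stages)
                if found is not None:
                    return found
                stages.pop()
            return None

        sol = search(0, [])
        if sol is not None:
            panels = []
            for idxs in sol:
                members = [pairs[i] for i in idxs]
                tms = [t for p in members for t in (p.tm_forward, p.tm_reverse)]
                panels.append(
                    PrimerPanel(
                        pairs=members,
                        annealing_temp=round(sum(tms) / len(tms), 1),
                        length_separation=length_separation,
                    )
                )
            return panels
    raise InputError("no feasible stage assignment found")  # pragma: no cover


def in_silico_pcr(
    panels: PrimerPanel | list[PrimerPanel],
    templates: AlignedSeqSet,
    allowed_mismatches: int = 2,
) -> list[tuple[str, str, int]]:
    """Predicted amplifications of a panel on templates sharing its coordinates.

    A template amplifies iff both primers bind with zero mismatches at their
    five 3'-terminal positions and at most ``allowed_mismatches`` elsewhere
    (gaps and Ns count as mismatches).  Returns (template id, target,
    amplicon length) sorted by template then length.
    """
    if isinstance(panels, PrimerPanel):
        panels = [panels]
    detections = []
    for panel in panels:
        for pair in panel.pairs:
            fwd = pair.forward
            rev_template = reverse_complement(pair.reverse)
            for rec in templates:
                fwd_win = rec.residues[pair.fwd_start : pair.fwd_start + len(fwd)]
                rev_win = rec.residues[pair.rev_end - len(rev_template) : pair.rev_end]
                if len(fwd_win) != len(fwd) or len(rev_win) != len(rev_template):
                    continue
                f_mm = [a != b for a, b in zip(fwd_win, fwd)]
                r_mm = [a != b for a, b in zip(rev_win, rev_template)]
                if any(f_mm[-PENTAMER:]) or any(r_mm[:PENTAMER]):
                    continue
                if (
                    sum(f_mm[:-PENTAMER]) <= allowed_mismatches
                    and sum(r_mm[PENTAMER:]) <= allowed_mismatches
                ):
                    detections.append((rec.id, pair.target, pair.amplicon_length))
    detections.sort(key=lambda d: (d[0], d[2], d[1]))
    return detections


def panel_report(panels: list[PrimerPanel], path: str | Path | None = None) -> pd.DataFrame:
    """Tabular panel summary (target, primers, length, Tms, stage)."""
    rows = []
    for stage, panel in enumerate(panels, start=1):
        for p in panel.pairs:
            rows.append(
                {
                    "target": p.target,
                    "forward": p.forward,
                    "reverse": p.reverse,
                    "amplicon_length": p.amplicon_length,
                    "tm_forward": p.tm_forward,
                    "tm_reverse": p.tm_reverse,
                    "stage": stage,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
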