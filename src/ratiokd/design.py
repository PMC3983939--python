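"""Cloning-oligonucleotide design for shRNA expression and reporter inserts.

Two deterministic designers are provided:

* the four-oligo scheme for shRNA expression plasmids, assembling a
  sense–loop–antisense hairpin insert with the human miR23 loop
  (``GCTTCCTGTCAC``) from two annealed duplexes, plus a verbatim two-oligo
  negative-control set (which carries its own, different loop);
* the two-oligo scheme for the red-reporter plasmids, inserting the 19-nt
  target into the reporter's 3′-UTR.

Throughout, the antisense arm is the *reverse complement* of the target: the
duplexes can only anneal as drawn when the second strand runs antiparallel.
A validator audits duplex complementarity, hairpin structure, end-overhang
compatibility (single-copy, unidirectional insertion) and the poly-T
transcription terminator, at the sequence level only — digestion and ligation
chemistry are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd

MIR23_LOOP = "GCTTCCTGTCAC"
TARGET_LENGTH = 19

#: verbatim negative-control oligos (sense-hairpin strand, then the
#: complementary strand); the control predates the miR23 design and embeds
#: the classical TTCAAGAGA loop.
CONTROL_OLIGO_TOP = (
    "GATCCCC" "ATGTACTGCGCGTGGAGAC" "TTCAAGAGA" "GTCTCCACGCGCAGTACAT" "TTTT"
)
CONTROL_OLIGO_BOTTOM = (
    "ATGTACTGCGCGTGGAGAC" "TCTCTTGAA" "GTCTCCACGCGCAGTACAT" "GGG"
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

OligoKind = Literal["shrna_four_oligo", "shrna_control_two_oligo", "reporter_two_oligo"]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class TargetSequence:
    """A 19-nt RNAi target (DNA alphabet, 5′→3′)."""

    name: str
    bases: str
    gene: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.bases)
        if len(self.bases) != TARGET_LENGTH:
            raise DesignError(
                f"target {self.name!r} must be {TARGET_LENGTH} nt, "
                f"got {len(self.bases)}"
            )


@dataclass(frozen=True)
class OligoSet:
    """A named set of synthesis-ready oligos plus its hairpin loop (if any)."""

    kind: OligoKind
    oligos: dict[str, str]
    loop: str = ""


@dataclass(frozen=True)
class CheckResult:
    name: str
    status: Literal["pass", "fail", "skipped"]
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    kind: OligoKind
    checks: tuple[CheckResult, ...]
    notes: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return all(c.status != "fail" for c in self.checks)

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if c.status == "fail"]


def _check_dna(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise DesignError(f"invalid base(s) {sorted(bad)}; alphabet is A/C/G/T")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement (DNA alphabet only)."""
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def design_shrna_oligos(target: TargetSequence) -> OligoSet:
    """Four-oligo set for an shRNA expression insert with the miR23 loop.

    With x the 19-nt target and y its reverse complement::

        #1-fwd: 5'-GATCCCC x GC-3'          (28 nt)
        #1-rev: 5'-ACAGGAAGC y GGG-3'       (31 nt)
        #2-fwd: 5'-TTCCTGTCAC y TTTT-3'     (33 nt)
        #2-rev: 5'-x GTG-3'                 (22 nt)

    Duplex #1 (#1-fwd/#1-rev) and duplex #2 (#2-fwd/#2-rev) are ligated in
    tandem; the assembled top strand reads
    ``GATCCCC + x + GCTTCCTGTCAC + y + TTTT`` (61 nt), i.e. sense–loop–
    antisense followed by the pol III poly-T terminator.
    """
    x = target.bases
    y = reverse_complement(x)
    return OligoSet(
        kind="shrna_four_oligo",
        oligos={
            "#1-fwd": f"GATCCCC{x}GC",
            "#1-rev": f"ACAGGAAGC{y}GGG",
            "#2-fwd": f"TTCCTGTCAC{y}TTTT",
            "#2-rev": f"{x}GTG",
        },
        loop=MIR23_LOOP,
    )


def design_reporter_oligos(target: TargetSequence) -> OligoSet:
    """Two-oligo set inserting the target into the red reporter's 3′-UTR.

    sense = target + TTCG, antisense = reverse_complement(target) + TTGC
    (23 nt each); the 19-bp core anneals, the 4-nt tails remain single-
    stranded overhangs for directional ligation.
    """
    x = target.bases
    return OligoSet(
        kind="reporter_two_oligo",
        oligos={
            "sense": f"{x}TTCG",
            "antisense": f"{reverse_complement(x)}TTGC",
        },
    )


def control_shrna_oligos() -> OligoSet:
    """The verbatim printed negative-control shRNA oligo pair."""
    return OligoSet(
        kind="shrna_control_two_oligo",
        oligos={"top": CONTROL_OLIGO_TOP, "bottom": CONTROL_OLIGO_BOTTOM},
        loop="TTCAAGAGA",
    )


def _mismatch_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _complementarity_check(
    name: str, expected: str, observed: str
) -> CheckResult:
    """Compare an observed strand with what perfect pairing would require."""
    if len(expected) != len(observed):
        return CheckResult(
            name,
            "fail",
            f"length mismatch: expected {len(expected)} nt, got {len(observed)}",
        )
    mism = _mismatch_positions(expected, observed)
    if mism:
        return CheckResult(
            name, "fail", f"mismatch at position(s) {mism} (0-based, 5'->3')"
        )
    return CheckResult(name, "pass")


def _hairpin_checks(top: str, bottom: str) -> tuple[list[CheckResult], list[str]]:
    checks: list[CheckResult] = []
    notes: list[str] = []

    # (ii) sense-loop-antisense structure of the assembled top strand
    sense = top[7 : 7 + TARGET_LENGTH]
    anti = reverse_complement(sense)
    idx = top.find(anti, 7 + TARGET_LENGTH)
    if idx < 0:
        checks.append(
            CheckResult(
                "hairpin_structure",
                "fail",
                "antisense arm (reverse complement of sense) not found "
                "downstream of the loop",
            )
        )
    else:
        loop = top[7 + TARGET_LENGTH : idx]
        checks.append(
            CheckResult("hairpin_structure", "pass", f"loop={loop!r} ({len(loop)} nt)")
        )
        notes.append(f"embedded loop {loop}")

    # (iii) terminal single-stranded extensions
    left = top[:4]  # 5' overhang of the top strand
    right = top[-4:]  # 3' extension of the top strand
    cross_compatible = reverse_complement(left) == right
    if cross_compatible:
        checks.append(
            CheckResult(
                "end_incompatibility",
                "fail",
                f"terminal extensions {left}/{right} can cross-anneal: "
                "head-to-tail tandem insertion is possible",
            )
        )
    else:
        checks.append(CheckResult("end_incompatibility", "pass"))
    for ext in (left, right):
        if reverse_complement(ext) == ext:
            notes.append(f"extension {ext} is palindromic (self-compatible end)")

    # (iv) pol III transcription terminator on the top strand
    tail = len(top) - len(top.rstrip("T"))
    if tail >= 4:
        checks.append(CheckResult("poly_t_terminator", "pass", f"{tail} terminal T"))
    else:
        checks.append(
            CheckResult(
                "poly_t_terminator",
                "fail",
                f"only {tail} terminal T on the top strand (need >= 4)",
            )
        )
    return checks, notes


def assembled_top_strand(oligo_set: OligoSet) -> str:
    """Top (sense-hairpin) strand of the annealed, ligated insert."""
    o = oligo_set.oligos
    if oligo_set.kind == "shrna_four_oligo":
        return o["#1-fwd"] + o["#2-fwd"]
    if oligo_set.kind == "shrna_control_two_oligo":
        return o["top"]
    raise DesignError("reporter oligo sets have no hairpin top strand")


def validate_hairpin(oligo_set: OligoSet) -> ValidationReport:
    """Sequence-level audit of an oligo set.

    For hairpin sets the report covers (i) duplex complementarity, (ii) the
    sense–loop–antisense architecture, (iii) incompatibility of the two
    terminal extensions (head-to-tail tandem prevention; individually
    palindromic ends are noted, not failed, since the upstream BglII-type
    overhang is legitimately self-complementary), and (iv) a ≥4-T terminator.
    Reporter sets get the core-complementarity and end checks only; hairpin
    checks are reported as skipped.
    """
    o = oligo_set.oligos
    checks: list[CheckResult] = []
    notes: list[str] = []

    if oligo_set.kind == "shrna_four_oligo":
        top = assembled_top_strand(oligo_set)
        # duplex #1: #1-rev pairs the CCC+x+GCTTCCTGT stretch of the top strand
        checks.append(
            _complementarity_check(
                "duplex1_complementarity", reverse_complement(top[4:35]), o["#1-rev"]
            )
        )
        # duplex #2: #2-rev pairs the CAC+y stretch
        checks.append(
            _complementarity_check(
                "duplex2_complementarity",
                reverse_complement(top[35 : 35 + len(o["#2-rev"])]),
                o["#2-rev"],
            )
        )
        hp, hn = _hairpin_checks(top, o["#2-rev"] + o["#1-rev"])
        checks += hp
        notes += hn
    elif oligo_set.kind == "shrna_control_two_oligo":
        top, bottom = o["top"], o["bottom"]
        checks.append(
            _complementarity_check(
                "duplex_complementarity", reverse_complement(top[4:-4]), bottom
            )
        )
        hp, hn = _hairpin_checks(top, bottom)
        checks += hp
        notes += hn
    elif oligo_set.kind == "reporter_two_oligo":
        sense, anti = o["sense"], o["antisense"]
        checks.append(
            _complementarity_check(
                "core_complementarity",
                reverse_complement(sense[:TARGET_LENGTH]),
                anti[:TARGET_LENGTH],
            )
        )
        left, right = sense[-4:], anti[-4:]
        if reverse_complement(left) == right:
            checks.append(
                CheckResult(
                    "end_incompatibility",
                    "fail",
                    f"tails {left}/{right} can cross-anneal",
                )
            )
        else:
            checks.append(CheckResult("end_incompatibility", "pass"))
        checks.append(CheckResult("hairpin_structure", "skipped"))
        checks.append(CheckResult("poly_t_terminator", "skipped"))
    else:
        raise DesignError(f"unknown oligo set kind {oligo_set.kind!r}")

    return ValidationReport(
        kind=oligo_set.kind, checks=tuple(checks), notes=tuple(notes)
    )


def load_target_table() -> pd.DataFrame:
    """The packaged 22-entry validation target table (name, sequence, gene)."""
    with resources.files("ratiokd.data").joinpath("targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_targets() -> list[TargetSequence]:
    df = load_target_table()
    return [
        TargetSequence(name=row["name"], bases=row["sequence"], gene=row["gene"])
        for _, row in df.iterrows()
    ]
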