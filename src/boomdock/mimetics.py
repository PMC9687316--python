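"""Interface-derived peptide mimetic design and DNA-binding-site overlap scoring.

Partner-protein residues observed at the BBM interface are reported as
comma-separated stretch lists ("G131, F132, X, D137", where X is a single
missing residue).  Design proceeds by (1) extracting maximal residue
stretches in which any number of *isolated* single-residue gaps may occur —
two or more consecutive missing residues terminate a stretch; (2) bridging
each gap with glycine to form a candidate peptide; (3) keeping candidates of
at least 8 residues.  Candidates are numbered by stretch length (longest
first), then BBM fragment, then source order — the convention behind the
published P1..P7 labels.  Finally, BBM residues at a peptide-complex
interface are scored by how many fall inside the fragment's DNA-binding
residue range.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .structio import THREE_TO_ONE

GAP = "X"

_TOKEN_RE = re.compile(r"^([A-Za-z])-?(\d+)$")


class ResidueListError(ValueError):
    """Raised for malformed interfacial residue-list notation."""


@dataclass
class InterfacialResidueList:
    """Parsed interface residue list of one partner protein.

    ``entries`` holds (one-letter code or "X", residue number) in strictly
    increasing number order; gap markers carry the implied number
    (previous + 1).  ``fragment`` names the BBM fragment whose complex the
    list came from; ``block_index`` preserves the source table order.
    """

    source: str
    entries: list[tuple[str, int]]
    fragment: str = ""
    block_index: int = 0
    repairs: list[str] = field(default_factory=list)

    def __post_init__(self):
        numbers = [n for _, n in self.entries]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ResidueListError(f"{self.source}: residue numbers not strictly increasing")

    @property
    def present(self) -> dict[int, str]:
        """number -> one-letter code for non-gap entries."""
        return {n: code for code, n in self.entries if code != GAP}


@dataclass
class ResidueStretch:
    """Maximal run of interface residues with only isolated single gaps."""

    source: str
    start: int
    end: int
    present: frozenset[int]
    gaps: frozenset[int]
    fragment: str = ""
    block_index: int = 0

    def __post_init__(self):
        self.present = frozenset(self.present)
        self.gaps = frozenset(self.gaps)
        full = set(range(self.start, self.end + 1))
        if self.present | self.gaps != full or self.present & self.gaps:
            raise ValueError("present and gaps must partition [start, end]")
        if {self.start, self.end} - self.present:
            raise ValueError("stretches must begin and end on present residues")
        for g in self.gaps:
            if g - 1 in self.gaps or g + 1 in self.gaps:
                raise ValueError("gaps must be isolated single residues")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PeptideCandidate:
    id: str
    sequence: str
    source: str
    fragment: str
    start: int
    end: int
    gaps: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BindingSiteRange:
    fragment_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("binding site range must have start <= end")

    def __contains__(self, number: int) -> bool:
        return self.start <= number <= self.end


@dataclass
class OverlapScore:
    peptide_id: str
    pose_id: str
    site: BindingSiteRange
    overlapping: frozenset[int]

    @property
    def count(self) -> int:
        return len(self.overlapping)


# ---------------------------------------------------------------------------
# Parsing

def parse_residue_list(text: str, source: str = "", fragment: str = "",
                       block_index: int = 0, lenient: bool = True) -> InterfacialResidueList:
    """Parse residue-list notation into an :class:`InterfacialResidueList`.

    Accepts comma-separated tokens ``<AA><number>``, ``<AA>-<number>`` or the
    gap marker ``X``, over one or several lines.  In lenient mode a token
    that breaks the strictly-increasing numbering (a table typo) is
    reassigned the only consistent number (previous + 1) and the repair is
    recorded; strict mode raises instead.
    """
    entries: list[tuple[str, int]] = []
    repairs: list[str] = []
    tokens = [t.strip() for line in text.splitlines()
              for t in line.split(",") if t.strip()]
    for token in tokens:
        if token.upper() == GAP:
            if not entries:
                raise ResidueListError(f"{source}: list cannot start with a gap marker")
            entries.append((GAP, entries[-1][1] + 1))
            continue
        m = _TOKEN_RE.match(token)
        if not m:
            raise ResidueListError(f"{source}: unknown token {token!r}")
        code, number = m.group(1).upper(), int(m.group(2))
        if code not in THREE_TO_ONE.values():
            raise ResidueListError(f"{source}: unknown amino-acid code in {token!r}")
        if entries and number <= entries[-1][1]:
            if not lenient:
                raise ResidueListError(
                    f"{source}: token {token!r} breaks monotonic numbering after "
                    f"{entries[-1][1]}")
            repaired = entries[-1][1] + 1
            repairs.append(f"{token} -> {code}{repaired} (monotonicity repair)")
            number = repaired
        entries.append((code, number))
    return InterfacialResidueList(source=source, entries=entries, fragment=fragment,
                                  block_index=block_index, repairs=repairs)


def parse_residue_table(text: str, fragment: str = "",
                        lenient: bool = True) -> list[InterfacialResidueList]:
    """Parse a sectioned residue-list file (``[protein]`` headers, one
    printed stretch per line) into one list per partner protein."""
    lists: list[InterfacialResidueList] = []
    name: str | None = None
    lines: list[str] = []

    def flush():
        if name is not None:
            lists.append(parse_residue_list("\n".join(lines), source=name,
                                            fragment=fragment,
                                            block_index=len(lists), lenient=lenient))

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            name, lines = line[1:-1].strip(), []
        elif name is None:
            raise ResidueListError(f"residue line before any [section] header: {line!r}")
        else:
            lines.append(line)
    flush()
    return lists


def bundled_residue_lists() -> list[InterfacialResidueList]:
    """The interfacial residue lists shipped with the package, fragment-1
    complexes first (the published study's input tables)."""
    out: list[InterfacialResidueList] = []
    for fragment in ("frag1", "frag2"):
        text = resources.files("boomdock.data") \
            .joinpath(f"interface_residues_{fragment}.txt").read_text()
        out.extend(parse_residue_table(text, fragment=fragment))
    return out


def bundled_binding_sites() -> dict[str, BindingSiteRange]:
    cfg = json.loads(resources.files("boomdock.data")
                     .joinpath("dna_binding_sites.json").read_text())
    return {k: BindingSiteRange(k, int(v[0]), int(v[1]))
            for k, v in cfg.items() if isinstance(v, list)}


# ---------------------------------------------------------------------------
# Stretch extraction and peptide construction

def extract_stretches(lst: InterfacialResidueList) -> list[ResidueStretch]:
    """Maximal stretches allowing isolated single-residue gaps.

    Consecutive present residues at most 2 apart (i.e. separated by at most
    one missing residue) stay in one stretch; a gap of two or more missing
    residues terminates it.  Stretches begin and end on present residues.
    """
    numbers = sorted(lst.present)
    stretches: list[ResidueStretch] = []
    i = 0
    while i < len(numbers):
        j = i
        while j + 1 < len(numbers) and numbers[j + 1] - numbers[j] <= 2:
            j += 1
        start, end = numbers[i], numbers[j]
        present = {n for n in numbers[i:j + 1]}
        gaps = set(range(start, end + 1)) - present
        stretches.append(ResidueStretch(source=lst.source, start=start, end=end,
                                        present=present, gaps=gaps,
                                        fragment=lst.fragment,
                                        block_index=lst.block_index))
        i = j + 1
    return stretches


def build_peptide(stretch: ResidueStretch, lst: InterfacialResidueList,
                  peptide_id: str = "") -> PeptideCandidate:
    """Peptide sequence for a stretch: source one-letter codes in position
    order with glycine substituted at every gap."""
    codes = lst.present
    seq = "".join("G" if n in stretch.gaps else codes[n]
                  for n in range(stretch.start, stretch.end + 1))
    return PeptideCandidate(id=peptide_id, sequence=seq, source=stretch.source,
                            fragment=stretch.fragment, start=stretch.start,
                            end=stretch.end, gaps=tuple(sorted(stretch.gaps)))


def select_peptides(lists: Sequence[InterfacialResidueList],
                    min_len: int = 8) -> list[PeptideCandidate]:
    """Design peptide candidates from interfacial residue lists.

    Stretches of at least ``min_len`` positions (bridged gaps included) are
    kept; ids P1.. are assigned ordering by stretch length (descending),
    then BBM fragment order as supplied, then source block order, then
    position.
    """
    fragment_rank: dict[str, int] = {}
    for lst in lists:
        fragment_rank.setdefault(lst.fragment, len(fragment_rank))
    picked: list[tuple[tuple, PeptideCandidate]] = []
    for lst in lists:
        for stretch in extract_stretches(lst):
            if stretch.length >= min_len:
                pep = build_peptide(stretch, lst)
                key = (-stretch.length, fragment_rank[lst.fragment],
                       lst.block_index, stretch.start)
                picked.append((key, pep))
    picked.sort(key=lambda kv: kv[0])
    out = []
    for i, (_, pep) in enumerate(picked, start=1):
        pep.id = f"P{i}"
        out.append(pep)
    return out


def peptides_fasta(peptides: Iterable[PeptideCandidate]) -> str:
    """FASTA serialization (headers: id|source|start-end|gaps)."""
    records = []
    for p in peptides:
        gaps = ",".join(str(g) for g in p.gaps) or "-"
        records.append(f">{p.id}|{p.source}|{p.start}-{p.end}|{gaps}\n{p.sequence}")
    return "\n".join(records) + ("\n" if records else "")


# ---------------------------------------------------------------------------
# DNA-binding-site overlap scoring

_3LETTER_RE = re.compile(r"^([A-Za-z]{3})\s*(\d+)$")


def parse_reported_residue(token: str) -> tuple[str, int]:
    """Parse a reported interface residue token such as 'LEU246'."""
    m = _3LETTER_RE.match(token.strip())
    if not m:
        raise ResidueListError(f"unknown residue token {token!r}")
    return m.group(1).upper(), int(m.group(2))


def overlap_score(interface_residues: Iterable[int], site: BindingSiteRange,
                  peptide_id: str = "", pose_id: str = "") -> OverlapScore:
    """Count interface residues (author numbering on the BBM fragment)
    falling inside a DNA-binding residue range."""
    overlapping = frozenset(n for n in interface_residues if n in site)
    return OverlapScore(peptide_id=peptide_id, pose_id=pose_id, site=site,
                        overlapping=overlapping)


def bundled_peptide_interfaces() -> list[dict]:
    """The reported per-peptide BBM interface residue lists."""
    cfg = json.loads(resources.files("boomdock.data")
                     .joinpath("peptide_interface_residues.json").read_text())
    return cfg["entries"]


def score_bundled_peptides() -> list[OverlapScore]:
    """Overlap scores for every reported peptide-BBM complex."""
    sites = bundled_binding_sites()
    scores = []
    for entry in bundled_peptide_interfaces():
        numbers = [parse_reported_residue(t)[1] for t in entry["residues"]]
        scores.append(overlap_score(numbers, sites[entry["site"]],
                                    peptide_id=entry["peptide"], pose_id=entry["pose"]))
    return scores
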