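"""Enumeration and validation of PG-X4 hexapeptide repeat motifs.

SynIDP tags are built from repeats of a ``P-G-X1-X2-X3-X4`` hexapeptide in
which the X positions are drawn from the 20 standard amino acids minus a
small set of forbidden residues.  The design rules implemented here:

* proline and cysteine are excluded from every X position (Pro would break
  the strict PG periodicity; Cys forms aggregation-prone disulfides);
* glycine must occur at least once among X1..X4 (flexibility);
* glycine is excluded from X4, which abuts the proline of the next repeat,
  so no GP dipeptide is created across the repeat boundary.

Motifs are enumerated per residue *multiset* (arrangements of the same four
residues are considered one design) and a deterministic canonical
arrangement is chosen for each multiset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


class MotifConfigError(ValueError):
    """Inconsistent motif specification (e.g. required residue forbidden)."""


class UnrealizableMotifError(ValueError):
    """The residue multiset admits no arrangement satisfying the spec."""


@dataclass(frozen=True)
class MotifSpec:
    """Constraints on the X positions of the PG-X4 repeat motif."""

    forbidden_global: frozenset[str] = frozenset({"P", "C"})
    required_residue: str = "G"
    min_required_count: int = 1
    forbidden_at_x4: frozenset[str] = frozenset({"G"})
    scaffold: tuple[str, str] = ("P", "G")
    n_x: int = 4
    alphabet: tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.required_residue in self.forbidden_global:
            raise MotifConfigError(
                f"required residue {self.required_residue!r} is globally forbidden"
            )
        if self.required_residue not in self.alphabet:
            raise MotifConfigError(
                f"required residue {self.required_residue!r} not in alphabet"
            )
        if self.n_x < 1:
            raise MotifConfigError("n_x must be >= 1")

    @property
    def x_alphabet(self) -> tuple[str, ...]:
        """Residues admissible at X positions (before the X4 restriction)."""
        return tuple(a for a in self.alphabet if a not in self.forbidden_global)


@dataclass(frozen=True)
class Motif:
    """A canonical arrangement of one admissible residue multiset."""

    x: tuple[str, ...]

    @property
    def multiset_key(self) -> str:
        return "".join(sorted(self.x))

    @property
    def sequence(self) -> str:
        """Hexapeptide in the PG phase, e.g. ``PGQSGL``."""
        return "PG" + "".join(self.x)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.sequence


@dataclass
class LibraryDesign:
    """An enumerated (deduplicated-by-multiset) motif library."""

    motifs: list[Motif]
    dedup_mode: str = "multiset"
    curation_excludes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


def admissible_multisets(spec: MotifSpec) -> list[tuple[str, ...]]:
    """All residue multisets (sorted tuples) realizable under ``spec``.

    A multiset is admissible when it draws only on the X alphabet, contains
    the required residue at least ``min_required_count`` times, and at least
    one of its residues may legally occupy X4.
    """
    out = []
    for combo in itertools.combinations_with_replacement(sorted(spec.x_alphabet), spec.n_x):
        if combo.count(spec.required_residue) < spec.min_required_count:
            continue
        if all(r in spec.forbidden_at_x4 for r in combo):
            continue  # no residue can take X4
        out.append(combo)
    return out


def realize_motif(multiset: Iterable[str], spec: MotifSpec | None = None) -> Motif:
    """Canonical arrangement of a residue multiset.

    Convention: X1..X4 sorted ascending; if that places a residue forbidden
    at X4 (glycine by default) last, it is swapped with X3.  Deterministic
    and invertible via :attr:`Motif.multiset_key`.
    """
    spec = spec or MotifSpec()
    residues = sorted(multiset)
    if len(residues) != spec.n_x:
        raise UnrealizableMotifError(
            f"multiset has {len(residues)} residues, expected {spec.n_x}"
        )
    for r in residues:
        if r in spec.forbidden_global or r not in spec.alphabet:
            raise UnrealizableMotifError(f"residue {r!r} not allowed at X positions")
    if residues.count(spec.required_residue) < spec.min_required_count:
        raise UnrealizableMotifError(
            f"multiset lacks required residue {spec.required_residue!r}"
        )
    x = list(residues)
    if x[-1] in spec.forbidden_at_x4:
        # swap with the next-lower position holding an admissible residue
        for i in range(len(x) - 2, -1, -1):
            if x[i] not in spec.forbidden_at_x4:
                x[-1], x[i] = x[i], x[-1]
                break
        else:
            raise UnrealizableMotifError(
                f"no arrangement of {''.join(residues)} keeps X4 clear of "
                f"{sorted(spec.forbidden_at_x4)}"
            )
    return Motif(x=tuple(x))


def enumerate_motifs(spec: MotifSpec | None = None) -> LibraryDesign:
    """Enumerate one canonical motif per admissible residue multiset.

    Order is lexicographic by multiset key, so the result is deterministic.
    """
    spec = spec or MotifSpec()
    motifs = [realize_motif(ms, spec) for ms in admissible_multisets(spec)]
    motifs.sort(key=lambda m: m.multiset_key)
    return LibraryDesign(motifs=motifs)


def apply_curation(design: LibraryDesign, excludes: Sequence[str]) -> LibraryDesign:
    """Drop motifs whose multiset key appears in an explicit exclusion list.

    Lets an enumerated library be reconciled against an externally curated
    design file whose selection rules are not derivable from the constraints.
    """
    excl = {"".join(sorted(e)) for e in excludes}
    kept = [m for m in design.motifs if m.multiset_key not in excl]
    return LibraryDesign(motifs=kept, curation_excludes=sorted(excl))


def build_repeat_unit(motif: Motif, n_repeats: int = 4, phase: str = "PG") -> str:
    """Tandem-repeat amino-acid unit for one motif.

    ``phase='PG'`` returns (P G X1 X2 X3 X4)*n; ``phase='GX'`` returns the
    cyclic rotation (G X1 X2 X3 X4 P)*n produced by cutting inside the
    Pro-Gly junction during digestion.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    hexapeptide = motif.sequence
    if phase == "GX":
        hexapeptide = hexapeptide[1:] + hexapeptide[0]
    elif phase != "PG":
        raise ValueError(f"unknown phase {phase!r}")
    return hexapeptide * n_repeats


def validate_library(design: LibraryDesign, spec: MotifSpec | None = None) -> pd.DataFrame:
    """Report every rule violation in a library; empty frame iff valid.

    Also flags duplicated multisets, which would defeat the
    'ignoring permutations' dedup contract.
    """
    spec = spec or MotifSpec()
    rows = []
    seen: dict[str, int] = {}
    for i, motif in enumerate(design.motifs):
        for r in motif.x:
            if r in spec.forbidden_global:
                rows.append((i, motif.sequence, "forbidden residue", r))
        if motif.x[-1] in spec.forbidden_at_x4:
            rows.append((i, motif.sequence, "forbidden at X4", motif.x[-1]))
        if motif.x.count(spec.required_residue) < spec.min_required_count:
            rows.append((i, motif.sequence, "missing required residue",
                         spec.required_residue))
        key = motif.multiset_key
        if key in seen:
            rows.append((i, motif.sequence, "duplicate multiset", key))
        seen.setdefault(key, i)
    return pd.DataFrame(rows, columns=["index", "motif", "violation", "detail"])


# ---------------------------------------------------------------------------
# I/O

def library_to_tsv(design: LibraryDesign, path) -> None:
    df = pd.DataFrame(
        {
            "motif": [m.sequence for m in design.motifs],
            "multiset_key": [m.multiset_key for m in design.motifs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def library_from_tsv(path) -> LibraryDesign:
    df = pd.read_csv(path, sep="\t")
    motifs = [Motif(x=tuple(seq[2:])) for seq in df["motif"]]
    return LibraryDesign(motifs=motifs)


def library_to_fasta(design: LibraryDesign, path, n_repeats: int = 4) -> None:
    """Write the n-repeat protein units as FASTA, one record per motif."""
    records = [
        SeqRecord(Seq(build_repeat_unit(m, n_repeats)), id=m.multiset_key,
                  description=m.sequence)
        for m in design.motifs
    ]
    SeqIO.write(records, path, "fasta")
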