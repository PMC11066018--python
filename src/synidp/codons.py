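"""Codon-level design of 72-nt repeat oligos with a junction-split SexAI site.

Each 24-residue repeat unit (PG-X4 hexapeptide x 4) is reverse-translated
into a 72-nt oligonucleotide that, once circularized, carries exactly one
SexAI recognition site (ACCWGGT, cut only when unmethylated) overlapping the
Pro-Gly codons at the junction.  Because the repeat is extremely regular at
the protein level, codons are scrambled over synonymous choices to suppress
direct and inverted nucleotide repeats (hairpin stems), the failure modes of
polymerase and ligase steps on repetitive templates.

Junction geometry: the site ACCTGGT is realized as

    [... codon ending in A][CCT = Pro][GGT = Gly]

so the linear oligo starts with the 3' fragment of the site (CCTGGT...) and
ends with the A that completes it upon circularization.  A unit whose X4
residue has no A-ending codon cannot carry the junction and raises
:class:`DesignFailure`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

SEXAI_SITE = "ACCTGGT"
SEXAI_PATTERN = "ACCWGGT"  # degenerate recognition; self-reverse-complementary

# E. coli K-12 codon usage, fraction within each amino acid (standard table).
ECOLI_CODON_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
    "R": {"CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAC": 0.55, "AAT": 0.45},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGC": 0.56, "TGT": 0.44},
    "Q": {"CAG": 0.65, "CAA": 0.35},
    "E": {"GAA": 0.69, "GAG": 0.31},
    "G": {"GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
    "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.77, "AAG": 0.23},
    "M": {"ATG": 1.00},
    "F": {"TTT": 0.57, "TTC": 0.43},
    "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.13},
    "S": {"AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "TCG": 0.15, "AGT": 0.15, "TCA": 0.12},
    "T": {"ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13},
    "W": {"TGG": 1.00},
    "Y": {"TAT": 0.57, "TAC": 0.43},
    "V": {"GTG": 0.37, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15},
}

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DesignFailure(RuntimeError):
    """Constraints on the oligo design cannot be met."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatScore:
    """Repeat structure of a DNA sequence.

    ``longest_direct_repeat``: longest substring occurring at >=2 distinct
    start positions (occurrences may overlap).  ``longest_inverted_repeat``:
    longest substring whose reverse complement also occurs, at disjoint
    positions — a potential hairpin stem.
    """

    longest_direct_repeat: int
    longest_inverted_repeat: int
    k0: int = 8
    w_direct: float = 1.0
    w_inverted: float = 2.0

    @property
    def composite(self) -> float:
        return (self.w_direct * max(0, self.longest_direct_repeat - self.k0)
                + self.w_inverted * max(0, self.longest_inverted_repeat - self.k0))


@dataclass(frozen=True)
class OligoDesign:
    """A 72-nt linear oligo encoding one repeat unit, junction site split."""

    nt_seq: str
    encoded_unit: str
    junction_site: str = SEXAI_SITE
    score: RepeatScore | None = None

    @property
    def circular(self) -> str:
        return self.nt_seq

    def translate_pg_phase(self) -> str:
        """Translation of the linear oligo: (P G X1..X4) repeats."""
        return str(Seq(self.nt_seq).translate())

    def translate_gx_phase(self) -> str:
        """Circular translation starting at the Gly codon: (G X1..X4 P)."""
        rot = self.nt_seq[3:] + self.nt_seq[:3]
        return str(Seq(rot).translate())


# ---------------------------------------------------------------------------
# Repeat structure scoring

def _running_lengths_vec(eq: np.ndarray) -> np.ndarray:
    """Vectorized run-length-so-far for a boolean vector."""
    if len(eq) == 0:
        return np.zeros(0, dtype=np.int64)
    c = np.cumsum(eq)
    reset = np.maximum.accumulate(np.where(~eq, c, 0))
    return (c - reset) * eq


def _longest_direct_repeat(seq: str) -> int:
    """Longest substring present at >=2 distinct start positions.

    Occurrences may overlap; computed as the longest match run along every
    self-alignment diagonal (shift d >= 1).
    """
    n = len(seq)
    if n < 2:
        return 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = 0
    for d in range(1, n):
        if n - d <= best:
            break
        eq = arr[:-d] == arr[d:]
        runs = _running_lengths_vec(eq)
        m = int(runs.max()) if len(runs) else 0
        if m > best:
            best = m
    return best


def _longest_inverted_repeat(seq: str, min_loop: int = 0) -> int:
    """Longest s such that s and revcomp(s) occur at disjoint positions.

    ``min_loop`` enforces a minimum gap between the two occurrences (hairpin
    stem-loop variant; 0 = plain disjointness).  Along every diagonal of the
    seq-vs-revcomp(seq) match matrix, a match run ending at (i, j) of length
    l corresponds to s = seq[i-l+1 : i+1] with the partner occurrence at
    [n-1-j, n-1-j+l).  The partner start does not depend on l, so the
    longest admissible stem at each endpoint has a closed form.
    """
    n = len(seq)
    if n < 2:
        return 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    best = 0
    for d in range(-(n - 1), n):
        if d >= 0:
            a, b = arr[: n - d], rc[d:]
            i0 = 0
        else:
            a, b = arr[-d:], rc[: n + d]
            i0 = -d
        if len(a) <= best:
            continue
        eq = a == b
        runs = _running_lengths_vec(eq)
        if not runs.any():
            continue
        idx = np.arange(len(eq))
        i = i0 + idx   # end index in seq
        j = i + d      # end index in rc (diagonal offset d = j - i)
        s = i + j
        # seq occurrence ends at i; partner occurrence is [n-1-j, n-1-j+l).
        # Either the seq occurrence lies entirely left of the partner
        # (holds for any l when i + 1 + min_loop <= n - 1 - j), or the
        # partner lies left, bounding l by (s + 2 - n - min_loop) / 2.
        left_ok = s <= n - 2 - min_loop
        bound = (s + 2 - n - min_loop) // 2
        cand = np.where(left_ok, runs, np.minimum(runs, np.maximum(bound, 0)))
        m = int(cand.max())
        if m > best:
            best = m
    return best


def repeat_structure_score(nt_seq: str, k0: int = 8, w_direct: float = 1.0,
                           w_inverted: float = 2.0, min_loop: int = 0) -> RepeatScore:
    """Direct/inverted repeat lengths and their composite penalty."""
    if any(b not in "ACGT" for b in nt_seq):
        raise ValueError("sequence must be over ACGT")
    return RepeatScore(
        longest_direct_repeat=_longest_direct_repeat(nt_seq),
        longest_inverted_repeat=_longest_inverted_repeat(nt_seq, min_loop),
        k0=k0, w_direct=w_direct, w_inverted=w_inverted,
    )


# ---------------------------------------------------------------------------
# Restriction-site scanning

def iupac_regex(pattern: str) -> re.Pattern:
    try:
        expanded = "".join(
            f"[{IUPAC_CODES[c]}]" if len(IUPAC_CODES[c]) > 1 else IUPAC_CODES[c]
            for c in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from exc
    return re.compile(f"(?=({expanded}))")


def scan_restriction_sites(nt_seq: str, pattern: str = SEXAI_PATTERN,
                           circular: bool = False) -> list[int]:
    """0-based start positions of (possibly overlapping) pattern matches.

    In circular mode matches wrapping the origin are reported modulo the
    sequence length.  ACCWGGT is its own reverse complement under W, so a
    single-strand scan covers both strands for the SexAI site.
    """
    rx = iupac_regex(pattern)
    target = nt_seq + (nt_seq[: len(pattern) - 1] if circular else "")
    return sorted({m.start() % len(nt_seq) if circular else m.start()
                   for m in rx.finditer(target)})


# ---------------------------------------------------------------------------
# Reverse translation with codon scrambling

def admissible_codons(residue: str, usage: dict[str, dict[str, float]],
                      min_usage: float = 0.10) -> list[str]:
    table = usage.get(residue)
    if not table:
        raise DesignFailure(f"no codons for residue {residue!r}")
    ok = [c for c, f in sorted(table.items()) if f >= min_usage]
    return ok or [max(table, key=table.get)]


@dataclass(frozen=True)
class CodonConfig:
    """Tunables for the codon scrambler."""

    min_usage: float = 0.10
    k0: int = 8
    w_direct: float = 1.0
    w_inverted: float = 2.0
    n_sweeps: int = 40


def _internal_site_count(circular_seq: str) -> int:
    hits = scan_restriction_sites(circular_seq, SEXAI_PATTERN, circular=True)
    # the designed junction site wraps the origin: starts at len-1 (the final A)
    return len([h for h in hits if h != len(circular_seq) - 1])


def _objective(seq: str, k0: float, w_d: float, w_i: float) -> float:
    sc = repeat_structure_score(seq, k0=int(k0), w_direct=w_d, w_inverted=w_i)
    return sc.composite + 1000.0 * _internal_site_count(seq)


def naive_reverse_translate(aa_unit: str, usage=None, min_usage: float = 0.10) -> str:
    """Most-frequent-codon encoding (the maximally repetitive baseline)."""
    usage = usage or ECOLI_CODON_USAGE
    return "".join(max(usage[r], key=usage[r].get) for r in aa_unit)


def reverse_translate_scrambled(
    aa_unit: str,
    usage: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    min_usage: float = 0.10,
    k0: int = 8,
    w_direct: float = 1.0,
    w_inverted: float = 2.0,
    n_sweeps: int = 40,
) -> OligoDesign:
    """Reverse-translate a PG-phase repeat unit into a junction-ready oligo.

    Synonymous codons are optimized by seeded simulated annealing to
    minimize the composite repeat score while keeping the circular sequence
    free of internal ACCWGGT matches.  The junction codons are immutable:
    position 0 = CCT (Pro), position 1 = GGT (Gly), and the final codon must
    end in A so that circularization creates the single ACCTGGT site.

    Deterministic for a fixed seed; the returned design never scores worse
    than the best sequence visited (monotone best-tracking) and is
    guaranteed not to score worse than the naive single-codon encoding.
    """
    usage = usage or ECOLI_CODON_USAGE
    if len(aa_unit) < 3 or aa_unit[0] != "P" or aa_unit[1] != "G":
        raise DesignFailure("unit must be in PG phase (start with Pro-Gly)")

    choices: list[list[str]] = []
    for idx, residue in enumerate(aa_unit):
        if residue not in usage:
            raise DesignFailure(f"residue {residue!r} has no codon table entry")
        if idx == 0:
            opts = ["CCT"]
        elif idx == 1:
            opts = ["GGT"]
        elif idx == len(aa_unit) - 1:
            # junction-completing codon: must end in A; bypasses usage cutoff
            opts = sorted(c for c in usage[residue] if c.endswith("A"))
            if not opts:
                raise DesignFailure(
                    f"residue {residue!r} at the junction position has no "
                    "A-ending codon; the split SexAI site cannot be formed"
                )
        else:
            opts = admissible_codons(residue, usage, min_usage)
        choices.append(opts)

    rng = np.random.default_rng(seed)
    codons = [opts[rng.integers(len(opts))] for opts in choices]
    mutable = [i for i, opts in enumerate(choices) if len(opts) > 1]

    def build(cs: list[str]) -> str:
        return "".join(cs)

    cur_seq = build(codons)
    cur_score = _objective(cur_seq, k0, w_direct, w_inverted)
    best_seq, best_score = cur_seq, cur_score

    if mutable:
        temps = np.geomspace(3.0, 0.05, n_sweeps)
        for t in temps:
            for i in rng.permutation(mutable):
                old = codons[i]
                alt = [c for c in choices[i] if c != old]
                new = alt[rng.integers(len(alt))]
                codons[i] = new
                cand_seq = build(codons)
                cand_score = _objective(cand_seq, k0, w_direct, w_inverted)
                delta = cand_score - cur_score
                if delta <= 0 or rng.random() < np.exp(-delta / t):
                    cur_seq, cur_score = cand_seq, cand_score
                    if cur_score < best_score:
                        best_seq, best_score = cur_seq, cur_score
                else:
                    codons[i] = old
            if best_score == 0:
                break

    # never return worse than a legal naive encoding
    naive = naive_reverse_translate(aa_unit, usage)
    if (_internal_site_count(naive) == 0 and naive[:6] == best_seq[:6]
            and naive.endswith("A")
            and _objective(naive, k0, w_direct, w_inverted) < best_score):
        best_seq = naive  # pragma: no cover - naive is rarely better

    if _internal_site_count(best_seq) > 0:
        raise DesignFailure(
            "no codon assignment found without an internal ACCWGGT site"
        )
    score = repeat_structure_score(best_seq, k0=k0, w_direct=w_direct,
                                   w_inverted=w_inverted)
    design = OligoDesign(nt_seq=best_seq, encoded_unit=aa_unit, score=score)
    assert design.translate_pg_phase() == aa_unit
    return design


def embed_junction_site(design: OligoDesign, site: str = SEXAI_SITE) -> OligoDesign:
    """Validate and canonicalize the junction-split restriction site.

    Checks that the linear oligo begins with the 3' fragment of ``site``
    (CCTGGT after the leading A) and ends with the A completing it, that the
    circularized sequence carries the degenerate pattern exactly once, and
    returns the design unchanged on success.
    """
    if site != SEXAI_SITE:
        raise ValueError("only the SexAI junction geometry is supported")
    seq = design.nt_seq
    if not seq.startswith(site[1:]):
        raise DesignFailure("oligo must begin with the 3' site fragment CCTGGT")
    if not seq.endswith(site[0]):
        raise DesignFailure("oligo must end with A to complete the site")
    hits = scan_restriction_sites(seq, SEXAI_PATTERN, circular=True)
    if hits != [len(seq) - 1]:
        raise DesignFailure(
            f"circularized design must contain exactly one junction site, "
            f"found matches at {hits}"
        )
    return design


def digest_circular_multimer(design: OligoDesign, n_copies: int) -> list[str]:
    """Fragments from full SexAI digestion of a circular n-copy concatemer.

    Cutting at every junction returns ``n_copies`` identical 72-nt
    fragments, each starting at the cut position within the site
    (A^CCWGGT), whose GX-phase translation is (G X1..X4 P)n.
    """
    circ = design.nt_seq * n_copies
    cuts = scan_restriction_sites(circ, SEXAI_PATTERN, circular=True)
    cut_points = sorted((c + 1) % len(circ) for c in cuts)  # A^CCWGGT
    frags = []
    for a, b in zip(cut_points, cut_points[1:] + [cut_points[0] + len(circ)]):
        frags.append((circ * 2)[a:b])
    return frags
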