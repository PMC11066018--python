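"""Sequencing-based verification of repeat libraries.

Reads derived from tandem-repeat concatemers of 72-nt units are aligned
against the designed reference units.  Because each reference is circular
(any rotation of the 72-mer is equivalent) a read is aligned in infix mode
against the unit tiled past the read length, in both orientations; the
optimal start position modulo 72 is the phase.  Verdicts follow the library
filtering rules: reads that are too short, align poorly, contain an in-frame
stop (nonsense), carry a long frame-disrupting indel region, or cover fewer
than three perfect 72-nt repeat copies are rejected.

The read simulator generates FASTQ with planted provenance (reference,
phase, orientation, error count) in the read names, so recovery can be
checked against ground truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import revcomp

UNIT_LEN = 72
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadAlignment:
    read_id: str
    best_reference: str
    orientation: str            # "forward" | "reverse_complement"
    phase_offset: int           # 0..71, start of the read in unit coordinates
    edit_distance: int
    n_subs: int
    indel_events: list[tuple[int, int]]  # (read position, +ins/-del length)
    n_perfect_repeats: int
    aligned_length: int
    cigar: str = ""

    @property
    def align_score(self) -> float:
        """Edit distance per aligned base (lower is better)."""
        return self.edit_distance / max(self.aligned_length, 1)


@dataclass(frozen=True)
class FilterThresholds:
    min_length: int = 100
    max_edit_rate: float = 0.10
    frameshift_window: int = 24   # nt before the frame must be restored
    min_perfect_repeats: int = 3


@dataclass
class FilterVerdict:
    reasons: list[str] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "pass" if not self.reasons else "fail"

    @property
    def passed(self) -> bool:
        return not self.reasons


def _parse_cigar(cigar: str) -> tuple[int, list[tuple[int, int]]]:
    """(n_substitutions, indel events as (query position, signed length))."""
    n_subs = 0
    events: list[tuple[int, int]] = []
    qpos = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "=M":
            qpos += n
        elif op == "X":
            n_subs += n
            qpos += n
        elif op == "I":  # insertion in query relative to reference
            events.append((qpos, n))
            qpos += n
        elif op == "D":
            events.append((qpos, -n))
    return n_subs, events


def count_perfect_repeats(read: str, reference_unit: str) -> int:
    """Number of exact, non-overlapping 72-nt unit copies found in the read.

    Any rotation of the unit counts as a copy; scanning is greedy from the
    left, jumping a full unit after each hit.
    """
    rotations = {reference_unit[i:] + reference_unit[:i]
                 for i in range(len(reference_unit))}
    n = 0
    i = 0
    L = len(reference_unit)
    while i + L <= len(read):
        if read[i:i + L] in rotations:
            n += 1
            i += L
        else:
            i += 1
    return n


def _align_one_orientation(query: str, reference_unit: str):
    n_tiles = (len(query) + 2 * len(reference_unit)) // len(reference_unit) + 1
    target = reference_unit * n_tiles
    res = edlib.align(query, target, mode="HW", task="path")
    start = res["locations"][0][0]
    end = res["locations"][0][1]
    return res["editDistance"], res["cigar"] or "", start % len(reference_unit), \
        (end - start + 1 if end is not None else len(query))


def align_read_circular(read: str, reference_unit: str,
                        read_id: str = "read", reference_id: str = "ref"
                        ) -> ReadAlignment:
    """Minimal-edit alignment of a read against a circular 72-nt reference.

    The reference is tiled beyond the read length and the read aligned in
    infix mode (free end gaps on the reference), which minimizes over all 72
    phase offsets in one pass; both orientations are tried.
    """
    if len(read) < 20:
        raise ValueError("read must be at least 20 nt")
    best = None
    for orientation, query in (("forward", read),
                               ("reverse_complement", revcomp(read))):
        dist, cigar, phase, alen = _align_one_orientation(query, reference_unit)
        if best is None or dist < best[0]:
            best = (dist, cigar, phase, alen, orientation, query)
    dist, cigar, phase, alen, orientation, query = best
    n_subs, events = _parse_cigar(cigar)
    return ReadAlignment(
        read_id=read_id,
        best_reference=reference_id,
        orientation=orientation,
        phase_offset=phase,
        edit_distance=dist,
        n_subs=n_subs,
        indel_events=events,
        n_perfect_repeats=count_perfect_repeats(query, reference_unit),
        aligned_length=alen,
        cigar=cigar,
    )


def align_read_to_library(read: str, references: dict[str, str],
                          read_id: str = "read") -> ReadAlignment:
    """Best circular alignment of a read over a reference library."""
    best: ReadAlignment | None = None
    for ref_id, unit in references.items():
        aln = align_read_circular(read, unit, read_id=read_id, reference_id=ref_id)
        if best is None or aln.edit_distance < best.edit_distance:
            best = aln
    assert best is not None
    return best


def _frame_from_phase(phase: int) -> int:
    """Offset into the read of the first full codon in the design frame."""
    return (-phase) % 3


def translation_in_design_frame(read: str, phase: int) -> str:
    off = _frame_from_phase(phase)
    coding = read[off: off + 3 * ((len(read) - off) // 3)]
    return str(Seq(coding).translate())


def classify_read(aln: ReadAlignment, read: str,
                  thresholds: FilterThresholds | None = None) -> FilterVerdict:
    """Apply the library filtering rules to one aligned read."""
    th = thresholds or FilterThresholds()
    verdict = FilterVerdict()
    if len(read) < th.min_length:
        verdict.reasons.append("too_short")
    if aln.align_score > th.max_edit_rate:
        verdict.reasons.append("poor_alignment")
    oriented = read if aln.orientation == "forward" else revcomp(read)
    if "*" in translation_in_design_frame(oriented, aln.phase_offset):
        verdict.reasons.append("nonsense")
    if _has_large_frameshift(aln, len(oriented), th.frameshift_window):
        verdict.reasons.append("large_frameshift")
    if aln.n_perfect_repeats < th.min_perfect_repeats:
        verdict.reasons.append("few_perfect_repeats")
    return verdict


def _has_large_frameshift(aln: ReadAlignment, read_len: int, window: int) -> bool:
    """True if a net frame disruption persists for more than ``window`` nt."""
    frame = 0
    shift_start = None
    for pos, length in sorted(aln.indel_events):
        if frame % 3 != 0 and shift_start is not None:
            if pos - shift_start > window:
                return True
        prev = frame
        frame += length
        if prev % 3 == 0 and frame % 3 != 0:
            shift_start = pos
        elif frame % 3 == 0:
            shift_start = None
    if frame % 3 != 0 and shift_start is not None:
        return read_len - shift_start > window
    return False


# ---------------------------------------------------------------------------
# Synthetic read generation

def simulate_reads(
    references: dict[str, str],
    n_reads: int,
    read_len: int = 250,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    revcomp_fraction: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[SeqRecord]:
    """Reads sampled from concatemerized designs with injected errors.

    Read names carry provenance: ``read<i>|ref=<id>|phase=<p>|orient=<o>|
    nerr=<n>``.  Deterministic for a fixed seed.
    """
    for r in (sub_rate, indel_rate, revcomp_fraction):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ref_ids = sorted(references)
    records = []
    bases = "ACGT"
    for i in range(n_reads):
        ref_id = ref_ids[rng.integers(len(ref_ids))]
        unit = references[ref_id]
        if read_len > 20 * len(unit):
            raise ValueError("read_len exceeds simulated concatemer length")
        phase = int(rng.integers(len(unit)))
        tiled = unit * ((read_len // len(unit)) + 2)
        clean = tiled[phase: phase + read_len]
        seqlist = []
        nerr = 0
        for base in clean:
            r = rng.random()
            if r < indel_rate / 2:           # deletion
                nerr += 1
                continue
            if r < indel_rate:               # insertion before the base
                seqlist.append(bases[rng.integers(4)])
                nerr += 1
            if rng.random() < sub_rate:
                alt = bases[rng.integers(4)]
                while alt == base:
                    alt = bases[rng.integers(4)]
                seqlist.append(alt)
                nerr += 1
            else:
                seqlist.append(base)
        seq = "".join(seqlist)
        orient = "rc" if rng.random() < revcomp_fraction else "fwd"
        if orient == "rc":
            seq = revcomp(seq)
        name = f"read{i}|ref={ref_id}|phase={phase}|orient={orient}|nerr={nerr}"
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fastq"))


# ---------------------------------------------------------------------------
# Library summary

def summarize_library(results: list[tuple[str, ReadAlignment, FilterVerdict]]
                      ) -> dict:
    """The four library-level summary fields.

    * unique (reference, edit-pattern) alignments observed;
    * unique read sequences passing all filters (proxied by read id when
      sequences are not retained);
    * distinct references hit in forward orientation by passing reads;
    * distinct references hit in reverse-complement orientation.
    """
    unique_alignments = {(a.best_reference, a.orientation, a.cigar)
                         for _, a, _ in results}
    passing = [(s, a) for s, a, v in results if v.passed]
    return {
        "n_unique_alignments": len(unique_alignments),
        "n_pass": len(passing),
        "n_unique_pass_sequences": len({s for s, _ in passing}),
        "n_forward_refs": len({a.best_reference for _, a in passing
                               if a.orientation == "forward"}),
        "n_revcomp_refs": len({a.best_reference for _, a in passing
                               if a.orientation == "reverse_complement"}),
    }


def results_table(results: list[tuple[str, ReadAlignment, FilterVerdict]]
                  ) -> pd.DataFrame:
    rows = []
    for seq, a, v in results:
        rows.append({
            "read_id": a.read_id,
            "reference": a.best_reference,
            "orientation": a.orientation,
            "phase_offset": a.phase_offset,
            "edit_distance": a.edit_distance,
            "n_subs": a.n_subs,
            "n_indel_events": len(a.indel_events),
            "n_perfect_repeats": a.n_perfect_repeats,
            "align_score": a.align_score,
            "status": v.status,
            "reasons": ";".join(v.reasons),
        })
    return pd.DataFrame(rows)
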