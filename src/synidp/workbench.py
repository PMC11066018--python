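"""End-to-end pipeline orchestration and synthetic fixture generation.

Ties the stages together: motif enumeration -> codon-scrambled oligo design
-> RCA/digestion simulation with size selection -> synthetic sequencing
reads -> alignment/filter QC -> solubility report.  One global seed is
fanned out into independent per-stage substreams, so a config + seed pair
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codons, motifs, qc, rca, scattering, solubility

log = logging.getLogger("synidp")


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "synidp_run"
    # motif stage
    x_alphabet: str = "AGSTQLH"
    n_motifs: int | None = 50
    n_repeats_unit: int = 4
    # codon stage
    codon_min_usage: float = 0.10
    codon_k0: int = 8
    codon_w_direct: float = 1.0
    codon_w_inverted: float = 2.0
    codon_n_sweeps: int = 12
    # RCA stage
    f_mc: float = 0.25
    c_blocking: int = 4
    n_units: int = 5000
    size_window: tuple[int, int] = (360, 576)
    # reads stage
    n_reads: int = 150
    read_len: int = 250
    sub_rate: float = 0.005
    indel_rate: float = 0.0
    revcomp_fraction: float = 0.1
    # QC thresholds
    qc_min_length: int = 100
    qc_max_edit_rate: float = 0.10
    qc_frameshift_window: int = 24
    qc_min_perfect_repeats: int = 3
    # solubility stage
    n_repeats_protein: int = 24
    threshold_standalone: int = 42
    threshold_fusion: int = 47

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["size_window"] = list(self.size_window)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "size_window" in d:
            d["size_window"] = tuple(d["size_window"])
        return cls(**d)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent per-stage integer seeds derived from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config_seed": config.seed, "files": {}, "stages": {}}

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = _sha256(path)

    # --- stage 1: motif enumeration -------------------------------------
    spec = motifs.MotifSpec(alphabet=tuple(sorted(set(config.x_alphabet) | {"G"}))
                            + ("P", "C"))
    library = motifs.enumerate_motifs(spec)
    if config.n_motifs is not None:
        library = motifs.LibraryDesign(motifs=library.motifs[: config.n_motifs])
    design_path = out / "design.tsv"
    motifs.library_to_tsv(library, design_path)
    record("design.tsv", design_path)
    manifest["stages"]["design"] = {"n_motifs": len(library)}
    log.info("design: %d motifs", len(library))

    # --- stage 2: oligo design ------------------------------------------
    oligo_rows = []
    designs: dict[str, codons.OligoDesign] = {}
    failures = []
    rng = np.random.default_rng(seeds[1])
    for motif in library:
        unit = motifs.build_repeat_unit(motif, config.n_repeats_unit)
        try:
            d = codons.reverse_translate_scrambled(
                unit, seed=int(rng.integers(2 ** 31)),
                min_usage=config.codon_min_usage, k0=config.codon_k0,
                w_direct=config.codon_w_direct,
                w_inverted=config.codon_w_inverted,
                n_sweeps=config.codon_n_sweeps)
            codons.embed_junction_site(d)
        except codons.DesignFailure as exc:
            failures.append({"motif": motif.sequence, "error": str(exc)})
            continue
        designs[motif.multiset_key] = d
        oligo_rows.append({
            "motif": motif.sequence, "id": motif.multiset_key,
            "nt_seq": d.nt_seq,
            "direct_repeat": d.score.longest_direct_repeat,
            "inverted_repeat": d.score.longest_inverted_repeat,
            "composite": d.score.composite,
        })
    oligo_path = out / "oligos.tsv"
    pd.DataFrame(oligo_rows).to_csv(oligo_path, sep="\t", index=False)
    record("oligos.tsv", oligo_path)
    manifest["stages"]["oligos"] = {"n_designed": len(designs),
                                    "n_failed": len(failures),
                                    "failures": failures}
    if not designs:
        raise RuntimeError("oligo stage produced no designs; aborting")

    # --- stage 3: RCA digestion + size selection ------------------------
    model = rca.ProtectionModel(f_mC=config.f_mc, c_blocking=config.c_blocking)
    digest = rca.simulate_digest(config.n_units, model, seed=seeds[2])
    sel = rca.size_select(digest.all_fragments, *config.size_window)
    frag_path = out / "fragments.tsv"
    pd.DataFrame({"length_bp": np.sort(digest.all_fragments)}).to_csv(
        frag_path, sep="\t", index=False)
    record("fragments.tsv", frag_path)
    manifest["stages"]["rca"] = {
        "q": model.q,
        "mean_internal_units": float(np.mean(digest.internal)) / rca.UNIT_LEN
        if len(digest.internal) else None,
        "count_fraction_in_window": float(sel.count_fraction),
        "mass_fraction_in_window": float(sel.mass_fraction),
    }

    # --- stage 4: synthetic reads ---------------------------------------
    refs = {mid: d.nt_seq for mid, d in designs.items()}
    records = qc.simulate_reads(
        refs, n_reads=config.n_reads, read_len=config.read_len,
        sub_rate=config.sub_rate, indel_rate=config.indel_rate,
        revcomp_fraction=config.revcomp_fraction, seed=seeds[3])
    reads_path = out / "reads.fastq"
    qc.write_fastq(records, reads_path)
    record("reads.fastq", reads_path)

    # --- stage 5: QC ----------------------------------------------------
    thresholds = qc.FilterThresholds(
        min_length=config.qc_min_length, max_edit_rate=config.qc_max_edit_rate,
        frameshift_window=config.qc_frameshift_window,
        min_perfect_repeats=config.qc_min_perfect_repeats)
    results = []
    for rec in records:
        seq = str(rec.seq)
        aln = qc.align_read_to_library(seq, refs, read_id=rec.id)
        verdict = qc.classify_read(aln, seq, thresholds)
        results.append((seq, aln, verdict))
    qc_table = qc.results_table(results)
    qc_path = out / "qc_reads.tsv"
    qc_table.to_csv(qc_path, sep="\t", index=False)
    record("qc_reads.tsv", qc_path)
    summary = qc.summarize_library(results)
    # planted-truth recovery for reads whose provenance is in the name
    correct = 0
    for rec, (seq2, aln, verdict) in zip(records, results):
        truth = dict(f.split("=") for f in rec.id.split("|")[1:])
        want = ("forward" if truth["orient"] == "fwd" else "reverse_complement")
        if aln.best_reference == truth["ref"] and aln.orientation == want:
            correct += 1
    summary["reference_recovery"] = correct / len(records) if records else 0.0
    manifest["stages"]["qc"] = summary
    qc_sum_path = out / "qc_summary.json"
    qc_sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    record("qc_summary.json", qc_sum_path)

    # --- stage 6: solubility report -------------------------------------
    sol_rows = []
    for motif in library:
        if motif.multiset_key not in designs:
            continue
        unit_gx = motifs.build_repeat_unit(motif, 1, phase="GX")
        construct = solubility.assemble_construct(solubility.ConstructSpec(
            unit=unit_gx, n_repeats=config.n_repeats_protein))
        tag = unit_gx * config.n_repeats_protein
        wh = solubility.wilkinson_harrison(tag)
        comp = solubility.composition_report(tag)
        sol_rows.append({
            "motif": motif.sequence,
            "hydropathy": solubility.mean_hydropathy(tag),
            "wh_class": wh["class"], "wh_probability": wh["probability"],
            "fraction_aromatic": comp["fraction_aromatic"],
            "fraction_positive": comp["fraction_positive"],
            "net_charge": comp["net_charge"],
            "construct_mass_da": solubility.average_mass(construct),
        })
    sol_path = out / "solubility.tsv"
    pd.DataFrame(sol_rows).to_csv(sol_path, sep="\t", index=False)
    record("solubility.tsv", sol_path)
    manifest["stages"]["solubility"] = {"n_reported": len(sol_rows)}

    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    record("config.yaml", config_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Fixture factory

def make_fixtures(kind: str, params: dict | None = None, seed: int = 0) -> dict:
    """Deterministic synthetic fixtures for tests and demos.

    kinds: ``reads`` (FASTQ records), ``scattering`` (noisy analytic
    profiles), ``cd`` (synthetic spectra), ``table1_style`` (labeled
    hydropathy scores with a planted integer separation threshold).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "reads":
        refs = params.pop("references")
        return {"records": qc.simulate_reads(refs, rng=rng, **params),
                "references": refs}
    if kind == "scattering":
        model = params.pop("model", "pev")
        q = np.asarray(params.pop("q", np.geomspace(0.012, 0.6, 120)))
        noise = params.pop("noise", 0.02)
        if model == "pev":
            pp = scattering.PEVParams(rg=params.pop("rg", 42.0),
                                      nu=params.pop("nu", 0.5))
            clean = scattering.pev_intensity(q, pp)
        elif model == "debye":
            clean = scattering.debye_chain(q, params.pop("rg", 42.0))
        elif model == "rod":
            clean = scattering.rod_form_factor(q, params.pop("length", 300.0))
        else:
            raise ValueError(f"unknown scattering fixture model {model!r}")
        sigma = noise * clean.I
        I = clean.I + (rng.normal(size=q.shape) * sigma if noise else 0.0)
        return {"profile": scattering.ScatteringProfile(q=q, I=np.maximum(I, 1e-12),
                                                        sigma=sigma),
                "truth": clean}
    if kind == "cd":
        shape = params.pop("shape", "coil")
        wl = np.arange(190.0, 261.0)
        if shape == "coil":
            el = (-8.0 * np.exp(-0.5 * ((wl - 197.0) / 4.0) ** 2)
                  + 1.5 * np.exp(-0.5 * ((wl - 215.0) / 5.0) ** 2))
        elif shape == "helix":
            el = (-6.0 * np.exp(-0.5 * ((wl - 208.0) / 4.0) ** 2)
                  - 6.0 * np.exp(-0.5 * ((wl - 222.0) / 4.0) ** 2)
                  + 8.0 * np.exp(-0.5 * ((wl - 193.0) / 3.0) ** 2))
        elif shape == "zero":
            el = np.zeros_like(wl)
        else:
            raise ValueError(f"unknown cd fixture shape {shape!r}")
        return {"wavelength_nm": wl, "ellipticity": el}
    if kind == "table1_style":
        t = int(params.pop("threshold", 42))
        n_per_class = int(params.pop("n_per_class", 6))
        gap = float(params.pop("gap", 0.5))
        insol = t - gap - rng.random(n_per_class) * 10.0
        sol = t + gap + rng.random(n_per_class) * 10.0
        # anchor the class extremes so the planted integer is exactly t
        insol[0] = t - gap
        sol[0] = t + gap
        scores = np.concatenate([insol, sol])
        labels = [False] * n_per_class + [True] * n_per_class
        return {"scores": scores, "labels": labels, "planted_threshold": t}
    raise ValueError(f"unknown fixture kind {kind!r}")
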