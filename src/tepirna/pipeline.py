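"""End-to-end orchestration of the simulated comparative study.

Two reusable experiment drivers:

* :func:`run_skim_study` -- simulate a genome skim for a set of family
  specs, map the reads, and return quantification, copy-number estimates
  and the divergence landscape together with the simulation truth.

* :func:`run_contrast_experiment` -- the two-species contrast at the heart
  of the analysis: a "balanced" host whose per-family piRNA output is
  proportional to TE transcript abundance (intact silencing) versus an
  "impaired" host whose piRNA output is independent of transcription.
  The driver simulates transcripts and a small-RNA pool, runs the
  small-RNA pipeline, joins TPM with piRNA RPM and returns the Pearson
  correlation -- significant for the balanced host, non-significant for
  the impaired one.

Both derive every random stream from one seed and can dump their tables
as TSV plus a JSON manifest of all parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .align import map_reads
from .annotation import annotate_transcripts, tpm_normalize
from .records import SequenceRecord, TERecord
from .repeatome import LandscapeResult, build_landscape, quantify_repeats
from .simulate import (
    FamilySpec,
    GenomeModel,
    SmallRNASpec,
    TranscriptSpec,
    random_references,
    simulate_genome_and_reads,
    simulate_small_rna,
    simulate_te_library,
    simulate_transcriptome,
)
from .smallrna import run_small_rna_pipeline
from .stats import build_te_pirna_table, correlate_by_class, pearson_with_p

__all__ = ["SkimStudy", "run_skim_study", "ContrastResult", "run_contrast_experiment"]


@dataclass
class SkimStudy:
    library: list[TERecord]
    quant: pd.DataFrame
    landscape: LandscapeResult
    family_truth: pd.DataFrame
    copy_truth: pd.DataFrame
    genome_size_bp: int
    total_read_bases: int


def run_skim_study(
    specs: Sequence[FamilySpec],
    genome_size_bp: int,
    coverage: float = 0.1,
    read_len: int = 150,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SkimStudy:
    """Simulate a skim for ``specs``, map it, quantify and bin divergence."""
    ss = np.random.SeedSequence(seed)
    lib_seed, sim_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    library = simulate_te_library(specs, lib_seed)
    sim = simulate_genome_and_reads(
        GenomeModel(genome_size_bp=genome_size_bp), library, specs,
        coverage=coverage, read_len=read_len, seed=sim_seed,
    )
    hits = map_reads(sim.reads, library, "genomic")
    quant = quantify_repeats(hits, sim.reads, library, genome_size_bp=genome_size_bp)
    landscape = build_landscape(hits, sim.reads, library)
    study = SkimStudy(library, quant, landscape, sim.family_truth, sim.copy_truth,
                      sim.genome_size_bp, sim.total_read_bases)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        quant.to_csv(outdir / "quant.tsv", sep="\t", index=False)
        landscape.table.to_csv(outdir / "landscape.tsv", sep="\t", index=False)
        sim.family_truth.to_csv(outdir / "family_truth.tsv", sep="\t", index=False)
        manifest = {
            "tool": f"tepirna {__version__}",
            "seed": seed,
            "genome_size_bp": genome_size_bp,
            "coverage": coverage,
            "read_len": read_len,
            "families": [asdict(s) for s in specs],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return study


@dataclass
class ContrastResult:
    condition: str  # balanced | impaired
    table: pd.DataFrame
    r: float
    p: float
    by_class: list
    true_weights: Mapping[str, float]


_CLASS_CYCLE = (
    ("LTR", "Ty1_copia", ("GAG", "PROT", "INT", "RT", "RH"), "Ty1"),
    ("LTR", "Ty3_gypsy", ("GAG", "PROT", "RT", "RH", "INT"), "Ty3"),
    ("LINE", None, ("RT",), "LINE"),
)


def run_contrast_experiment(
    seed: int = 0,
    balanced: bool = True,
    n_families: int = 30,
    n_small_rna: int = 20000,
    noise_cv: float = 0.2,
    consensus_len: int = 2000,
    n_replicates: int = 3,
    outdir: str | Path | None = None,
) -> ContrastResult:
    """Simulate one species and test piRNA RPM vs TE transcript TPM.

    In the balanced condition the small-RNA generator's per-family piRNA
    weights equal the family's expected transcript abundance times
    lognormal noise with coefficient of variation ``noise_cv``; in the
    impaired condition the weights are drawn independently of expression
    with the same marginal spread.
    """
    ss = np.random.SeedSequence([seed, 0 if balanced else 1])
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    rng = np.random.default_rng(seeds[0])

    fam_specs = []
    tx_specs = []
    class_of = {}
    expr_mean = {}
    for i in range(n_families):
        subclass, superfam, arch, clade = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        fid = f"fam{i:03d}"
        fam_specs.append(FamilySpec(fid, subclass, superfam,
                                    consensus_len=consensus_len, copy_number=0))
        mean = float(rng.lognormal(mean=np.log(60.0), sigma=1.0))
        expr_mean[fid] = mean
        tx_specs.append(TranscriptSpec(
            id=f"{fid}_tx", architecture=arch, clade=clade,
            true_subclass={"Ty1": "LTR/Ty1_copia", "Ty3": "LTR/Ty3_gypsy",
                           "LINE": "LINE"}[clade],
            length=consensus_len, mean_count=mean, dispersion=0.05,
        ))
        class_of[fid] = {"Ty1": "Ty1_copia", "Ty3": "Ty3_gypsy", "LINE": "LINE"}[clade]

    library = simulate_te_library(fam_specs, seeds[1])
    samples = [f"testis_rep{i + 1}" for i in range(n_replicates)]
    txome = simulate_transcriptome(tx_specs, samples, seed=seeds[2])
    lengths = pd.Series({t.id: len(t.seq) for t in txome.transcripts})
    tpm = tpm_normalize(txome.counts, lengths)
    te_tpm = tpm.mean(axis=1)
    te_tpm.index = [tid[: -len("_tx")] for tid in te_tpm.index]

    sigma = float(np.sqrt(np.log(1.0 + noise_cv**2)))
    if balanced:
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n_families)
        weights = {f: float(te_tpm[f]) * float(noise[i])
                   for i, f in enumerate(te_tpm.index)}
    else:
        draws = rng.lognormal(mean=np.log(60.0), sigma=1.0, size=n_families)
        weights = {f: float(draws[i]) for i, f in enumerate(te_tpm.index)}

    contaminants = random_references("rrna", 3, 1500, seeds[3])
    hairpins = random_references("mir", 40, 80, seeds[3] + 1)
    srna_spec = SmallRNASpec(
        n_reads=n_small_rna, pirna_fraction=0.5, mirna_fraction=0.3,
        contaminant_fraction=0.1, family_weights=weights,
    )
    pool = simulate_small_rna(srna_spec, library, contaminants, hairpins,
                              seed=seeds[4])

    tx_to_family = {f"{f}_tx": f for f in te_tpm.index}
    result = run_small_rna_pipeline(
        pool.reads,
        te_refs=list(library) + list(txome.transcripts),
        contaminant_refs=contaminants,
        hairpin_refs=hairpins,
        target_to_family=tx_to_family,
    )

    annotation = annotate_transcripts(txome.domain_hits)
    assert (annotation["assigned_class"] != "unclassified").all()
    table = build_te_pirna_table(te_tpm, result.abundance, pd.Series(class_of))
    r, p = pearson_with_p(table["te_tpm"], table["total_rpm"])
    by_class = correlate_by_class(table)
    condition = "balanced" if balanced else "impaired"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "matched_table.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(c) for c in by_class]).to_csv(
            outdir / "correlations.tsv", sep="\t", index=False)
        manifest = {
            "tool": f"tepirna {__version__}",
            "seed": seed,
            "condition": condition,
            "n_families": n_families,
            "n_small_rna": n_small_rna,
            "noise_cv": noise_cv,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ContrastResult(condition, table, r, p, by_class, weights)
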