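"""Synthetic single-cell DIA dataset generator with known ground truth.

The generator emulates the statistical structure of a nanowell-chip
single-cell DIA experiment at the level of the post-search precursor report:

* per-protein base abundance ``alpha_p`` and per-precursor offset ``beta_j``
  (ionization efficiency) in log2 space;
* a cell-size axis: log2 intensity grows linearly with log2 cell diameter
  (coefficient ``size_coefficient``); diameters are uniform over the sorting
  gate.  Histone proteins do *not* carry the size term — chromatin content
  tracks ploidy rather than cell volume, which is exactly why histones work
  as a per-cell normalization reference;
* an optional per-cell nuisance level shared by *all* proteins
  (``cell_nuisance_sd``), the quantity the histone normalization stage is
  supposed to remove;
* per-chip batch effects: additive log2 shift and a multiplicative scale on
  the noise, matching the location/scale model the batch correction assumes;
* gene-module covariation: disjoint groups of proteins share a per-(module,
  cell) random effect, giving the GO rollup and PCA real structure;
* bovine (serum carry-over) and human keratin contaminant precursors;
* intensity-dependent missingness (logistic in true log2 intensity, MNAR)
  combined with completely random dropout (MCAR), and q-values of which a
  configurable fraction exceeds the identification threshold.

Everything is reproducible from the seed, and the realized truth (all drawn
vectors and the true intensity matrix) is returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import ProteinAnnotation, default_histone_genes, flag_contaminant_classes
from .errors import ParameterError
from .io_formats import GeneSet, GeneSetCollection, PrecursorRecord

_NON_KR = sorted(set("ACDEFGHILMNPQSTVWY"))  # amino acids minus K/R


@dataclass
class SyntheticTruth:
    """Generator parameters; realized draws live in :class:`RealizedTruth`."""

    n_cells: int = 48
    n_proteins: int = 200
    precursors_per_protein_mean: float = 3.2
    protein_base_mean_log2: float = 14.0
    protein_base_sd_log2: float = 2.0
    precursor_offset_sd_log2: float = 1.0
    size_coefficient: float = 1.0
    histones_track_size: bool = False
    diameter_range_um: tuple[float, float] = (17.0, 36.0)
    chip_size: int = 48
    batch_shift_sd_log2: float = 0.5
    batch_scale_sd: float = 0.0
    n_modules: int = 10
    module_size: int = 12
    module_effect_sd: float = 0.5
    cell_nuisance_sd: float = 0.0
    noise_sd: float = 0.3
    mnar_midpoint_log2: float = 13.0
    mnar_slope: float = 0.6
    mcar_rate: float = 0.03
    contaminant_fraction: float = 0.05
    n_histones: int = 6
    histone_abundance_boost_log2: float = 2.0
    q_fail_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 4:
            raise ParameterError("n_cells must be >= 4")
        if self.n_proteins < 10:
            raise ParameterError("n_proteins must be >= 10")
        for name in ("mcar_rate", "contaminant_fraction", "q_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} must be in [0, 1]")
        for name in (
            "noise_sd",
            "mnar_slope",
            "precursor_offset_sd_log2",
            "protein_base_sd_log2",
            "module_effect_sd",
            "cell_nuisance_sd",
            "batch_shift_sd_log2",
            "batch_scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.chip_size < 2:
            raise ParameterError("chip_size must be >= 2")
        lo, hi = self.diameter_range_um
        if not 0 < lo < hi:
            raise ParameterError("diameter_range_um must satisfy 0 < low < high")


@dataclass
class RealizedTruth:
    """All realized draws of one simulation, for recovery tests."""

    params: SyntheticTruth
    cells: list[str]
    diameters: pd.Series
    chips: pd.Series
    batch_shifts: dict[str, float]
    batch_scales: dict[str, float]
    alpha: pd.Series  # per accession
    beta: pd.Series  # per precursor key
    protein_of_precursor: pd.Series
    module_of_protein: dict[str, int]
    module_effects: pd.DataFrame  # module × cell
    nuisance: pd.Series  # per cell
    size_term: pd.Series  # per cell (log2)
    histone_accessions: list[str]
    contaminant_precursors: set[str] = field(default_factory=set)
    x_true: pd.DataFrame | None = None  # precursor × cell true log2 intensity

    def to_json_dict(self) -> dict:
        d = {
            "params": dataclasses.asdict(self.params),
            "cells": self.cells,
            "diameters": self.diameters.to_dict(),
            "chips": self.chips.to_dict(),
            "batch_shifts": self.batch_shifts,
            "batch_scales": self.batch_scales,
            "histone_accessions": self.histone_accessions,
            "module_of_protein": self.module_of_protein,
            "n_precursors": int(len(self.beta)),
            "n_contaminant_precursors": len(self.contaminant_precursors),
        }
        return d


@dataclass
class SyntheticDataset:
    records: list[PrecursorRecord]
    annotations: dict[str, ProteinAnnotation]
    metadata: pd.DataFrame
    genesets: GeneSetCollection
    truth: RealizedTruth


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _make_sequence(rng: np.random.Generator, n_fragments: int, taken: set[str]) -> tuple[str, list[str]]:
    """Random protein sequence with exactly ``n_fragments`` tryptic fragments
    of length 6-31 (terminator included), each globally unique."""
    fragments = []
    for _ in range(n_fragments):
        for _attempt in range(20):
            length = int(rng.integers(6, 31))
            body = "".join(rng.choice(_NON_KR, size=length - 1))
            frag = body + ("K" if rng.random() < 0.5 else "R")
            if frag not in taken:
                taken.add(frag)
                fragments.append(frag)
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw a unique tryptic fragment")
    return "".join(fragments), fragments


def simulate_dataset(truth: SyntheticTruth) -> SyntheticDataset:
    """Draw one synthetic dataset (report records, FASTA annotations, cell
    metadata, gene sets) together with its realized ground truth."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n_cells = truth.n_cells

    cells = [f"cell_{i:03d}" for i in range(n_cells)]
    lo, hi = truth.diameter_range_um
    diameters = pd.Series(rng.uniform(lo, hi, n_cells), index=cells, name="diameter_um")
    n_chips = int(np.ceil(n_cells / truth.chip_size))
    chip_ids = [f"chip_{1 + i // truth.chip_size:02d}" for i in range(n_cells)]
    chips = pd.Series(chip_ids, index=cells, name="chip_id")
    chip_names = sorted(set(chip_ids))

    batch_shifts = {
        c: (float(rng.normal(0.0, truth.batch_shift_sd_log2)) if n_chips > 1 else 0.0)
        for c in chip_names
    }
    batch_scales = {
        c: float(max(0.2, rng.normal(1.0, truth.batch_scale_sd))) for c in chip_names
    }

    # --- proteins -----------------------------------------------------------
    histone_pool = sorted(default_histone_genes())
    if truth.n_histones > len(histone_pool):
        raise ParameterError("n_histones exceeds the shipped histone gene list")
    accessions: list[str] = []
    gene_of: dict[str, str] = {}
    organism_of: dict[str, str] = {}
    histone_accessions: list[str] = []
    for i in range(truth.n_proteins):
        acc = f"P{i:05d}"
        accessions.append(acc)
        organism_of[acc] = "Homo sapiens"
        if i < truth.n_histones:
            gene_of[acc] = histone_pool[i]
            histone_accessions.append(acc)
        else:
            gene_of[acc] = f"GENE{i:04d}"

    # module membership: disjoint blocks of non-histone proteins
    module_of_protein: dict[str, int] = {}
    cursor = truth.n_histones
    for m in range(truth.n_modules):
        block = accessions[cursor : cursor + truth.module_size]
        if not block:
            break
        for acc in block:
            module_of_protein[acc] = m
        cursor += truth.module_size

    alpha_vals = rng.normal(truth.protein_base_mean_log2, truth.protein_base_sd_log2, truth.n_proteins)
    alpha_vals[: truth.n_histones] = (
        truth.protein_base_mean_log2
        + truth.histone_abundance_boost_log2
        + rng.normal(0.0, 0.5, truth.n_histones)
    )
    alpha = dict(zip(accessions, alpha_vals))

    prec_counts = 1 + rng.poisson(max(truth.precursors_per_protein_mean - 1.0, 0.0), truth.n_proteins)

    # --- contaminant proteins ----------------------------------------------
    n_human_prec = int(prec_counts.sum())
    n_contam_prec = int(round(truth.contaminant_fraction * n_human_prec / max(1e-12, 1.0 - truth.contaminant_fraction)))
    contam_accessions: list[str] = []
    contam_counts: list[int] = []
    i_bov = i_ker = 0
    remaining = n_contam_prec
    while remaining > 0:
        k = int(min(remaining, rng.integers(2, 5)))
        if (i_bov + i_ker) % 2 == 0:
            acc = f"B{i_bov:05d}"
            organism_of[acc] = "Bos taurus"
            gene_of[acc] = f"BTGENE{i_bov:03d}"
            i_bov += 1
        else:
            acc = f"K{i_ker:05d}"
            organism_of[acc] = "Homo sapiens"
            gene_of[acc] = f"KRT{i_ker + 1}"
            i_ker += 1
        contam_accessions.append(acc)
        alpha[acc] = float(rng.normal(truth.protein_base_mean_log2, truth.protein_base_sd_log2))
        contam_counts.append(k)
        remaining -= k

    # --- sequences and precursors ------------------------------------------
    taken_fragments: set[str] = set()
    sequences: dict[str, str] = {}
    fragment_lists: dict[str, list[str]] = {}
    for acc, count in list(zip(accessions, prec_counts)) + list(
        zip(contam_accessions, contam_counts)
    ):
        n_frag = int(max(count, rng.integers(5, 26)))
        seq, frags = _make_sequence(rng, n_frag, taken_fragments)
        sequences[acc] = seq
        fragment_lists[acc] = frags

    prec_keys: list[str] = []
    prec_seq: list[str] = []
    prec_charge: list[int] = []
    prec_protein: list[str] = []
    prec_group: list[tuple[str, ...]] = []
    beta_list: list[float] = []
    contaminant_precursors: set[str] = set()

    def add_precursor(acc: str, frag: str, contaminant: bool, group: tuple[str, ...]):
        charge = int(rng.integers(2, 4))
        key = f"{frag}/{charge}"
        prec_keys.append(key)
        prec_seq.append(frag)
        prec_charge.append(charge)
        prec_protein.append(acc)
        prec_group.append(group)
        beta_list.append(float(rng.normal(0.0, truth.precursor_offset_sd_log2)))
        if contaminant:
            contaminant_precursors.add(key)

    for acc, count in zip(accessions, prec_counts):
        for j in range(count):
            add_precursor(acc, fragment_lists[acc][j], False, (acc,))
    human_pool = accessions
    for acc, count in zip(contam_accessions, contam_counts):
        bovine = organism_of[acc] == "Bos taurus"
        for j in range(count):
            group = (acc,)
            if bovine and rng.random() < 0.5:
                # shared peptide: ambiguous human/bovine protein group
                partner = human_pool[int(rng.integers(0, len(human_pool)))]
                group = (partner, acc)
            add_precursor(acc, fragment_lists[acc][j], True, group)

    n_prec = len(prec_keys)
    beta = np.array(beta_list)
    alpha_per_prec = np.array([alpha[p] for p in prec_protein])

    # --- true log2 intensities ---------------------------------------------
    log2_d = np.log2(diameters.to_numpy())
    size_term = truth.size_coefficient * (log2_d - log2_d.mean())
    nuisance = (
        rng.normal(0.0, truth.cell_nuisance_sd, n_cells)
        if truth.cell_nuisance_sd > 0
        else np.zeros(n_cells)
    )
    module_effects = rng.normal(0.0, truth.module_effect_sd, (truth.n_modules, n_cells))
    if truth.module_effect_sd == 0:
        module_effects[:] = 0.0

    histone_set = set(histone_accessions)
    size_gets = np.array(
        [
            1.0 if (truth.histones_track_size or p not in histone_set) else 0.0
            for p in prec_protein
        ]
    )
    module_idx = np.array([module_of_protein.get(p, -1) for p in prec_protein])
    shift_per_cell = np.array([batch_shifts[c] for c in chip_ids])
    scale_per_cell = np.array([batch_scales[c] for c in chip_ids])

    x = alpha_per_prec[:, None] + beta[:, None]
    x = x + size_gets[:, None] * size_term[None, :]
    x = x + nuisance[None, :]
    has_module = module_idx >= 0
    x[has_module] += module_effects[module_idx[has_module]]
    eps = rng.normal(0.0, truth.noise_sd, (n_prec, n_cells)) if truth.noise_sd > 0 else np.zeros((n_prec, n_cells))
    x = x + shift_per_cell[None, :] + scale_per_cell[None, :] * eps

    # --- missingness and q-values ------------------------------------------
    if truth.mnar_slope > 0:
        p_obs = _sigmoid(truth.mnar_slope * (x - truth.mnar_midpoint_log2))
        observed = rng.random((n_prec, n_cells)) < p_obs
    else:
        observed = np.ones((n_prec, n_cells), dtype=bool)
    if truth.mcar_rate > 0:
        observed &= rng.random((n_prec, n_cells)) >= truth.mcar_rate

    q_bad = rng.random((n_prec, n_cells)) < truth.q_fail_rate
    q_vals = np.where(
        q_bad,
        rng.uniform(0.010001, 0.3, (n_prec, n_cells)),
        rng.uniform(0.0, 0.0099999, (n_prec, n_cells)),
    )

    # --- records (cell-major, like per-run exports) -------------------------
    records: list[PrecursorRecord] = []
    for c_idx, cell in enumerate(cells):
        rows = np.flatnonzero(observed[:, c_idx])
        for j in rows:
            group = prec_group[j]
            records.append(
                PrecursorRecord(
                    run_id=cell,
                    protein_group=group,
                    gene_symbols=tuple(gene_of[a] for a in group),
                    organisms=tuple(organism_of[a] for a in group),
                    modified_sequence=prec_seq[j],
                    charge=prec_charge[j],
                    q_value=float(q_vals[j, c_idx]),
                    intensity=float(2.0 ** x[j, c_idx]),
                )
            )

    # --- companion artifacts -------------------------------------------------
    annotations = {
        acc: ProteinAnnotation(
            accession=acc,
            gene_symbol=gene_of[acc],
            organism=organism_of[acc],
            sequence=sequences[acc],
        )
        for acc in list(accessions) + contam_accessions
    }
    flag_contaminant_classes(annotations)

    metadata = pd.DataFrame(
        {
            "cell_id": cells,
            "chip_id": chip_ids,
            "diameter_um": diameters.to_numpy(),
            "passed_image_qc": True,
        }
    )

    genesets = GeneSetCollection()
    module_members: dict[int, list[str]] = {}
    for acc, m in module_of_protein.items():
        module_members.setdefault(m, []).append(gene_of[acc])
    for m in sorted(module_members):
        term_id = f"GO:SYN{m:04d}"
        genesets.sets[term_id] = GeneSet(
            term_id, f"synthetic module {m} process", frozenset(module_members[m])
        )
    genesets.sets["GO:SYNX"] = GeneSet(
        "GO:SYNX", "unmapped control term", frozenset({"ZZZ1", "ZZZ2", "ZZZ3"})
    )

    realized = RealizedTruth(
        params=truth,
        cells=cells,
        diameters=diameters,
        chips=chips,
        batch_shifts=batch_shifts,
        batch_scales=batch_scales,
        alpha=pd.Series(alpha),
        beta=pd.Series(beta, index=prec_keys),
        protein_of_precursor=pd.Series(prec_protein, index=prec_keys),
        module_of_protein=module_of_protein,
        module_effects=pd.DataFrame(module_effects, columns=cells),
        nuisance=pd.Series(nuisance, index=cells),
        size_term=pd.Series(size_term, index=cells),
        histone_accessions=histone_accessions,
        contaminant_precursors=contaminant_precursors,
        x_true=pd.DataFrame(x, index=prec_keys, columns=cells),
    )
    return SyntheticDataset(records, annotations, metadata, genesets, realized)


def default_study_scale(seed: int = 0, **overrides) -> SyntheticTruth:
    """Study-scale defaults: one 48-cell experiment split over two chips,
    ~1100 proteins at ~3.2 precursors each, with missingness such that
    post-QC per-cell precursor counts and ≥50 %-coverage completeness are of
    the same order as a real single-cell DIA run."""
    params = dict(
        n_cells=48,
        n_proteins=1100,
        precursors_per_protein_mean=3.2,
        chip_size=24,
        size_coefficient=1.0,
        batch_shift_sd_log2=0.5,
        n_modules=10,
        module_size=12,
        module_effect_sd=0.5,
        noise_sd=0.3,
        mnar_midpoint_log2=13.0,
        mnar_slope=0.6,
        mcar_rate=0.03,
        contaminant_fraction=0.05,
        n_histones=6,
        q_fail_rate=0.05,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset in exactly the formats the IO module reads."""
    from pathlib import Path

    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "precursor_report.tsv",
        "fasta": outdir / "proteins.fasta",
        "metadata": outdir / "cells.tsv",
        "gmt": outdir / "genesets.gmt",
        "truth": outdir / "truth.json",
    }
    io_formats.write_precursor_report(dataset.records, paths["report"])
    io_formats.write_fasta(dataset.annotations.values(), paths["fasta"])
    io_formats.write_metadata(dataset.metadata, paths["metadata"])
    io_formats.write_gmt(dataset.genesets, paths["gmt"])
    io_formats.write_manifest(dataset.truth.to_json_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
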