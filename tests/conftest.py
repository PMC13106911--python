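"""Shared fixtures: a small synthetic dataset and a hand-built filter fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scprot import (
    PrecursorRecord,
    ProteinAnnotation,
    SyntheticTruth,
    flag_contaminant_classes,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_truth() -> SyntheticTruth:
    return SyntheticTruth(
        n_cells=12,
        n_proteins=60,
        chip_size=6,
        n_modules=4,
        module_size=8,
        n_histones=4,
        mnar_midpoint_log2=12.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate_dataset(small_truth)


def _rec(cell, accs, orgs, genes, seq, q=0.001, intensity=1024.0, charge=2):
    return PrecursorRecord(
        run_id=cell,
        protein_group=tuple(accs),
        gene_symbols=tuple(genes),
        organisms=tuple(orgs),
        modified_sequence=seq,
        charge=charge,
        q_value=q,
        intensity=intensity,
    )


@pytest.fixture(scope="session")
def filter_fixture():
    """Hand-constructed 10-cell / 50-precursor cascade fixture.

    Construction (all truth values follow by counting, not by running the
    filters):

    * precursors A01–A20 (human): observed with good q in cells c01–c08;
      additionally A01–A03 in c09 and A01–A04 in c10 (167 records);
    * B01–B10 (human): observed in c01–c04 (40 records);
    * C01–C10 (human): observed in c01–c03 (30 records); C01 additionally
      has 7 records with q >= 0.01 in c04–c10;
    * K01–K05 (keratins KRT1–KRT5): observed in all 10 cells (50 records);
    * V01–V03 (pure bovine groups): observed in c01–c02 (6 records);
    * M01–M02 (mixed human+bovine groups): observed in c01 (2 records).

    Expected cascade (q < 0.01, human-unambiguous, keratin removal, per-cell
    minimum of 5 precursors, coverage >= 50 % of remaining cells):
    302 -> 295 -> 287 -> 237 records; 40 precursors x 10 cells; cells c09 and
    c10 removed (3 and 4 observed precursors); coverage keeps A (8/8) and B
    (4/8, boundary) and drops C (3/8): 30 precursors x 8 cells, 200 observed.
    """
    cells = [f"c{i:02d}" for i in range(1, 11)]
    annotations: dict[str, ProteinAnnotation] = {}
    seq_stub = "MAAAAAKGGGGGGRTTTTTTK"
    for i in range(1, 41):
        acc = f"HP{i:02d}"
        annotations[acc] = ProteinAnnotation(acc, f"G{i:02d}", "Homo sapiens", seq_stub)
    for i in range(1, 6):
        acc = f"KP{i}"
        annotations[acc] = ProteinAnnotation(acc, f"KRT{i}", "Homo sapiens", seq_stub)
    for i in range(1, 4):
        acc = f"BP{i}"
        annotations[acc] = ProteinAnnotation(acc, f"BT{i}", "Bos taurus", seq_stub)
    flag_contaminant_classes(annotations)

    records: list[PrecursorRecord] = []

    def human(i):
        acc = f"HP{i:02d}"
        return [acc], ["Homo sapiens"], [annotations[acc].gene_symbol]

    # A01-A20 in c01-c08, plus A01-A03 in c09 and A01-A04 in c10
    for i in range(1, 21):
        accs, orgs, genes = human(i)
        for cell in cells[:8]:
            records.append(_rec(cell, accs, orgs, genes, f"APEPTIDE{i:02d}"))
    for i in range(1, 4):
        accs, orgs, genes = human(i)
        records.append(_rec("c09", accs, orgs, genes, f"APEPTIDE{i:02d}"))
    for i in range(1, 5):
        accs, orgs, genes = human(i)
        records.append(_rec("c10", accs, orgs, genes, f"APEPTIDE{i:02d}"))
    # B01-B10 in c01-c04
    for i in range(1, 11):
        accs, orgs, genes = human(20 + i)
        for cell in cells[:4]:
            records.append(_rec(cell, accs, orgs, genes, f"BPEPTIDE{i:02d}"))
    # C01-C10 in c01-c03, plus 7 bad-q records for C01 in c04-c10
    for i in range(1, 11):
        accs, orgs, genes = human(30 + i)
        for cell in cells[:3]:
            records.append(_rec(cell, accs, orgs, genes, f"CPEPTIDE{i:02d}"))
    accs, orgs, genes = human(31)
    for cell, q in zip(cells[3:], [0.02, 0.5, 0.011, 0.01, 0.99, 0.2, 0.3]):
        records.append(_rec(cell, accs, orgs, genes, "CPEPTIDE01", q=q))
    # keratins K01-K05 in all cells
    for i in range(1, 6):
        acc = f"KP{i}"
        for cell in cells:
            records.append(
                _rec(cell, [acc], ["Homo sapiens"], [f"KRT{i}"], f"KPEPTIDE{i:02d}")
            )
    # pure bovine V01-V03 in c01-c02
    for i in range(1, 4):
        acc = f"BP{i}"
        for cell in cells[:2]:
            records.append(_rec(cell, [acc], ["Bos taurus"], [f"BT{i}"], f"VPEPTIDE{i:02d}"))
    # mixed human+bovine M01-M02 in c01
    for i in range(1, 3):
        records.append(
            _rec(
                "c01",
                [f"HP{i:02d}", "BP1"],
                ["Homo sapiens", "Bos taurus"],
                [f"G{i:02d}", "BT1"],
                f"MPEPTIDE{i:02d}",
            )
        )

    expected = {
        "total": 302,
        "after_q": 295,
        "after_species": 287,
        "after_keratin": 237,
        "n_precursors": 40,
        "n_cells": 10,
        "cells_removed": ["c09", "c10"],
        "min_precursors": 5,
        "after_coverage_precursors": 30,
        "final_observed": 200,
    }
    return records, annotations, expected


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
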