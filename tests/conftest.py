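"""Shared fixtures: hand-made guides, small designed libraries, and
deterministically planted count tensors."""

from __future__ import annotations

import numpy as np
import pytest

from titracrispr import (
    CountTensor,
    GeneTarget,
    LibrarySpec,
    ParentGuide,
    design_library,
    synthetic_genes,
)

# 50% GC, max T-run 1, passes all sequence filters
GOOD_SPACER = "ACGTACGTACGTACGTACGT"


def make_parent(spacer: str = GOOD_SPACER, gene_id: str = "toy",
                role: str | None = "SG1", pam_offset: int = 1) -> ParentGuide:
    from Bio.Seq import Seq

    proto = str(Seq(spacer).reverse_complement())
    gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
    return ParentGuide(gene_id=gene_id, pam_offset=pam_offset, protospacer=proto,
                       spacer=spacer, gc_fraction=gc, role=role)


def planted_tensor(
    rhos: dict[str, float],
    reference: str = "negC_ref",
    hours=(0, 2, 4, 6, 10, 12, 14),
    doublings_per_hour: float = 1.0,
    barcodes=("CTTTCA", "ATCATG", "GCATGG"),
    base: float = 10_000.0,
) -> CountTensor:
    """Counts that follow exact exponential competition: guide g in every
    barcode has count round(base * 2**(rho_g * generations)).  The
    reference (rho = 0) is included automatically."""
    all_rhos = dict(rhos)
    all_rhos.setdefault(reference, 0.0)
    hours = np.asarray(hours, dtype=float)
    gens = hours * doublings_per_hour
    guides = sorted(all_rhos)
    counts = np.zeros((len(guides), len(barcodes), len(hours)), dtype=np.int64)
    for gi, g in enumerate(guides):
        traj = np.rint(base * np.exp2(all_rhos[g] * gens)).astype(np.int64)
        counts[gi, :, :] = traj[None, :]
    return CountTensor(guides, list(barcodes), hours, counts)


@pytest.fixture(scope="session")
def toy_genes() -> list[GeneTarget]:
    return synthetic_genes(4, length=600, seed=11)


@pytest.fixture(scope="session")
def toy_library(toy_genes) -> LibrarySpec:
    return design_library(toy_genes, n_negc=6, seed=11)
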