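#!/usr/bin/env python
"""Materialize the two cohorts every downstream analysis runs on.

Writes (a) the reference cohort transcribed from the study's candidate
tables (9 families, 14 sequenced affected participants, 5 candidate
variants, 100-person control counts) and (b) one seeded simulated cohort
of the same shape with planted causal variants and 20 single-gate decoys.
"""

from pathlib import Path

from famvar.fixture import write_fixture
from famvar.io_formats import write_cohort, write_gene_list
from famvar.synthetic_cohort import CohortSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fixture_dir = OUT / "fixture"
    paths = write_fixture(fixture_dir)
    print(f"reference cohort: {len(paths)} files under {fixture_dir}")

    sim_dir = OUT / "simulated"
    sim = generate_cohort(CohortSpec(seed=2023))
    write_cohort(sim.cohort, sim_dir)
    for source, genes in sim.gene_lists.items():
        write_gene_list(genes, sim_dir / f"genes_{source.lower()}.txt")
    n_planted = len(sim.planted)
    n_decoys = len(sim.decoy_labels)
    print(
        f"simulated cohort: {len(sim.cohort.variants)} variants "
        f"({n_planted} planted, {n_decoys} decoys), "
        f"{len(sim.cohort.sequenced_individuals())} sequenced cases -> {sim_dir}"
    )


if __name__ == "__main__":
    main()
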