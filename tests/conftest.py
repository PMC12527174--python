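from __future__ import annotations

import numpy as np
import pytest

from u1scan.annotation import build_databases, load_annotation
from u1scan.registers import RNU1_1
from u1scan.simulate import (
    FixtureSpec,
    PlantedSite,
    PlantedVariant,
    generate_genome,
    generate_tpm,
    generate_variants,
)


def rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    """Hand-laid-out two-gene annotation: one 2-exon plus-strand gene, one
    gene with two transcript variants sharing a donor junction, and an MT
    decoy that must be excluded."""
    d = tmp_path_factory.mktemp("toy")
    rng = np.random.default_rng(123)
    chr1 = rand_dna(rng, 600)
    mt = rand_dna(rng, 200)
    (d / "genome.fa").write_text(f">chr1\n{chr1}\n>MT\n{mt}\n")
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\ttoy\tgene\t11\t210\t.\t+\t.\tID=gA",
            "chr1\ttoy\tmRNA\t11\t210\t.\t+\t.\tID=gA.t1;Parent=gA",
            "chr1\ttoy\texon\t11\t60\t.\t+\t.\tID=gA.t1.e1;Parent=gA.t1",
            "chr1\ttoy\texon\t161\t210\t.\t+\t.\tID=gA.t1.e2;Parent=gA.t1",
            "chr1\ttoy\tgene\t251\t550\t.\t-\t.\tID=gB",
            "chr1\ttoy\tmRNA\t251\t550\t.\t-\t.\tID=gB.t1;Parent=gB",
            "chr1\ttoy\texon\t251\t330\t.\t-\t.\tID=gB.t1.e1;Parent=gB.t1",
            "chr1\ttoy\texon\t431\t490\t.\t-\t.\tID=gB.t1.e2;Parent=gB.t1",
            "chr1\ttoy\texon\t521\t550\t.\t-\t.\tID=gB.t1.e3;Parent=gB.t1",
            "chr1\ttoy\tmRNA\t251\t550\t.\t-\t.\tID=gB.t2;Parent=gB",
            "chr1\ttoy\texon\t251\t330\t.\t-\t.\tID=gB.t2.e1;Parent=gB.t2",
            "chr1\ttoy\texon\t521\t550\t.\t-\t.\tID=gB.t2.e2;Parent=gB.t2",
            "MT\ttoy\tgene\t11\t150\t.\t+\t.\tID=gMT",
            "MT\ttoy\tmRNA\t11\t150\t.\t+\t.\tID=gMT.t1;Parent=gMT",
            "MT\ttoy\texon\t11\t150\t.\t+\t.\tID=gMT.t1.e1;Parent=gMT.t1",
        ]
    )
    (d / "annotation.gff3").write_text(gff + "\n")
    return {"dir": d, "fasta": str(d / "genome.fa"), "gff": str(d / "annotation.gff3"),
            "chr1": chr1, "mt": mt}


@pytest.fixture(scope="session")
def toy_models(toy_files):
    return load_annotation(toy_files["gff"], toy_files["fasta"])


def standard_spec(seed: int = 7) -> FixtureSpec:
    """The planted fixture used across the suite: one site per register
    plus donor-anchored COM sites, a micro-intron-free layout, a minus
    strand gene and an organellar decoy."""
    return FixtureSpec(
        seed=seed,
        n_genes=4,
        exons_per_gene=(3, 4),
        exon_length=(50, 110),
        intron_length=(70, 160),
        minus_strand_genes=(2,),
        variants_per_gene=2,
        include_mt_decoy=True,
        planted_sites=(
            PlantedSite(0, "donor", ("donor", 0, -3), "COM"),
            PlantedSite(0, "donor", ("donor", 1, -1), "BS1"),
            PlantedSite(1, "intronic", ("donor", 0, 17), "COM"),
            PlantedSite(1, "exonic", ("donor", 1, -13), "BS2"),
            PlantedSite(2, "donor", ("donor", 0, -5), "BA1", mismatches=1),
            PlantedSite(2, "acceptor", ("acceptor", 0, -4), "ALS"),
            PlantedSite(3, "intronic", ("donor", 0, 30), "BA2"),
            PlantedSite(3, "acceptor", ("acceptor", 1, -2), "ALA", mismatches=0),
        ),
        planted_variants=(
            PlantedVariant(0, 0, -3),
            PlantedVariant(0, 0, 5),
            PlantedVariant(0, 1, 1),
            PlantedVariant(1, 0, 2),
            PlantedVariant(1, 0, -2, significance="Likely pathogenic"),
            PlantedVariant(1, 1, 6, condition="hereditary cancer syndrome"),
            PlantedVariant(2, 0, 8),
            PlantedVariant(2, 1, -12),
            PlantedVariant(3, 0, 4, significance="Benign"),
            PlantedVariant(3, 0, 7),
        ),
    )


@pytest.fixture(scope="session")
def planted_fixture(tmp_path_factory):
    d = tmp_path_factory.mktemp("planted")
    spec = standard_spec()
    fx = generate_genome(spec, d)
    var_path, var_truth = generate_variants(spec, fx, d)
    tpm_path, members_path, psi_truth = generate_tpm(spec, fx, d)
    return {
        "spec": spec, "fixture": fx, "dir": d,
        "variants": var_path, "variants_truth": var_truth,
        "tpm": tpm_path, "members": members_path, "psi_truth": psi_truth,
    }


@pytest.fixture(scope="session")
def planted_db(planted_fixture):
    fx = planted_fixture["fixture"]
    models = load_annotation(str(fx.gff_path), str(fx.fasta_path))
    return build_databases(models, str(fx.fasta_path))


@pytest.fixture(scope="session")
def binding():
    return RNU1_1
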