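"""The rescuable-variant filter: pathogenic, canonical-window, pre-mismatch rules."""

import numpy as np
import pytest

from u1scan.annotation import load_annotation
from u1scan.simulate import FixtureSpec, PlantedVariant, generate_genome, generate_variants
from u1scan.variants import (
    CANONICAL_TARGET_CONSENSUS,
    VariantRecord,
    annotate_offsets,
    filter_pathogenic,
    parse_variants,
    select_rescuable,
    survey,
)


def _v(offset=None, wt=None, sig="Pathogenic", cond="retinal dystrophy",
       ref="A", alt="G", vid="v1"):
    return VariantRecord(vid, "chr1", 100, ref, alt, sig, cond,
                         transcript_id="t1", offset=offset, wild_type_base=wt)


def test_canonical_consensus_is_reverse_complement_of_binding():
    assert "".join(CANONICAL_TARGET_CONSENSUS[o] for o in
                   [-3, -2, -1, 1, 2, 3, 4, 5, 6, 7, 8]) == "CAGGTAAGTAT"


class TestPathogenicFilter:
    @pytest.mark.parametrize("sig,cond,kept", [
        ("Pathogenic", "retinitis pigmentosa", True),
        ("pathogenic", "deafness", True),
        ("Likely pathogenic", "deafness", False),
        ("Likely benign", "deafness", False),
        ("Benign", "deafness", False),
        ("", "deafness", False),
        ("Pathogenic", "hereditary cancer syndrome", False),
        ("Pathogenic", "Carcinoma of colon", False),
        ("Pathogenic", "neoplasm of ovary", False),
    ])
    def test_rules(self, sig, cond, kept):
        [out] = filter_pathogenic([_v(sig=sig, cond=cond)])
        assert (out.reason is None) == kept


class TestRescuable:
    @pytest.mark.parametrize("offset,wt,kept,reason", [
        (+1, "G", False, "position_plus1_plus2"),
        (+2, "T", False, "position_plus1_plus2"),
        (+5, "G", True, None),
        (-3, "C", True, None),
        (-3, "T", False, "pre_mismatched"),
        (+9, "A", False, "outside_canonical_window"),
        (-4, "A", False, "outside_canonical_window"),
    ])
    def test_rules(self, offset, wt, kept, reason):
        [out] = select_rescuable([_v(offset=offset, wt=wt)])
        assert (out.reason is None) == kept
        if reason:
            assert out.reason == reason

    def test_indels_excluded(self):
        [out] = select_rescuable([_v(offset=5, wt="G", ref="AT", alt="A")])
        assert out.reason == "not_single_nucleotide"

    def test_filter_order_independent(self):
        variants = [
            _v(offset=o, wt=CANONICAL_TARGET_CONSENSUS.get(o, "A"), sig=s, cond=c, vid=f"v{i}")
            for i, (o, s, c) in enumerate([
                (5, "Pathogenic", "x"), (1, "Pathogenic", "x"),
                (5, "Benign", "x"), (5, "Pathogenic", "cancer"),
                (-3, "Pathogenic", "x"), (9, "Pathogenic", "x"),
            ])
        ]
        a = {v.variant_id for v in select_rescuable(filter_pathogenic(variants))
             if v.reason is None}
        b = {v.variant_id for v in filter_pathogenic(select_rescuable(variants))
             if v.reason is None}
        assert a == b == {"v0", "v4"}

    def test_every_excluded_has_one_reason(self):
        variants = [_v(offset=o, wt="G", vid=f"v{o}") for o in (1, 5, 9)]
        out = select_rescuable(filter_pathogenic(variants))
        assert len(out) == len(variants)
        for v in out:
            assert v.reason is None or isinstance(v.reason, str)


class TestParsing:
    def test_rows_without_coordinates_dropped(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "variant_id\tchrom\tpos\tref\talt\tsignificance\tcondition\n"
            "v1\tchr1\t100\tA\tG\tPathogenic\tdeafness\n"
            "v2\tchr1\t\tA\tG\tPathogenic\tdeafness\n"
            "v3\tchr1\t200\tC\tT\tBenign\tdeafness\n"
        )
        recs = parse_variants(str(p))
        assert [r.variant_id for r in recs] == ["v1", "v3"]

    def test_missing_column_is_config_error(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("id\tchrom\n1\tchr1\n")
        with pytest.raises(ValueError, match="columns"):
            parse_variants(str(p))

    def test_column_map_override(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("VariationID\tChromosome\tStart\tRef\tAlt\tClinicalSignificance\tPhenotypeList\n"
                     "77\tchr1\t100\tA\tG\tPathogenic\tdeafness\n")
        recs = parse_variants(str(p), {
            "id": "VariationID", "chrom": "Chromosome", "pos": "Start",
            "ref": "Ref", "alt": "Alt", "significance": "ClinicalSignificance",
            "condition": "PhenotypeList"})
        assert recs[0].variant_id == "77" and recs[0].pos == 100


def test_offset_annotation_against_fixture(planted_fixture):
    """Offsets computed from the genome agree with where variants were planted."""
    fx = planted_fixture["fixture"]
    models = load_annotation(str(fx.gff_path), str(fx.fasta_path))
    recs = parse_variants(str(planted_fixture["variants"]))
    annotated = annotate_offsets(recs, models, str(fx.fasta_path))
    truth = {
        line.split("\t")[0]: line.split("\t")[1:]
        for line in planted_fixture["variants_truth"].read_text().splitlines()[1:]
    }
    for v in annotated:
        off, wt, _ = truth[v.variant_id]
        assert v.offset == int(off), v
        assert v.wild_type_base == wt


def test_survey_matches_planted_truth(planted_fixture):
    fx = planted_fixture["fixture"]
    models = load_annotation(str(fx.gff_path), str(fx.fasta_path))
    recs = parse_variants(str(planted_fixture["variants"]))
    result = survey(recs, models, str(fx.fasta_path))
    truth = {
        line.split("\t")[0]: line.split("\t")[3] == "True"
        for line in planted_fixture["variants_truth"].read_text().splitlines()[1:]
    }
    assert {v.variant_id for v in result.kept} == {k for k, s in truth.items() if s}
    assert {v.variant_id for v in result.excluded} == {k for k, s in truth.items() if not s}
    assert result.n_variants == len(result.kept)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_randomized_variant_truth(tmp_path, seed):
    """Random offset/significance/condition combinations: the kept set always
    equals the rule-derived truth."""
    rng = np.random.default_rng(seed)
    offsets = [int(o) for o in rng.choice([o for o in range(-12, 13) if o != 0], 12)]
    sigs = [str(s) for s in rng.choice(
        ["Pathogenic", "Likely pathogenic", "Benign", "Uncertain significance"], 12,
        p=[0.6, 0.2, 0.1, 0.1])]
    conds = [str(c) for c in rng.choice(
        ["degenerative retinal disease", "familial cancer of breast", "myopathy"], 12)]
    spec = FixtureSpec(
        seed=seed, n_genes=2, exons_per_gene=(3, 3),
        exon_length=(60, 90), intron_length=(80, 120),
        planted_variants=tuple(
            PlantedVariant(int(rng.integers(2)), int(rng.integers(2)), o, s, c)
            for o, s, c in zip(offsets, sigs, conds)
        ),
    )
    fx = generate_genome(spec, tmp_path / "g")
    var_path, truth_path = generate_variants(spec, fx, tmp_path / "g")
    models = load_annotation(str(fx.gff_path), str(fx.fasta_path))
    result = survey(parse_variants(str(var_path)), models, str(fx.fasta_path))
    truth = {
        line.split("\t")[0]: line.split("\t")[3] == "True"
        for line in truth_path.read_text().splitlines()[1:]
    }
    assert {v.variant_id for v in result.kept} == {k for k, s in truth.items() if s}
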