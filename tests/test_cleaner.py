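import collections
from dataclasses import replace

import pytest

from igclean import (
    average_quality,
    clean_dataset,
    clean_read,
    generate_clean_fixture,
    read_fasta_qual,
    reverse_complement,
)
from igclean.cleaner import LOG_COLUMNS

from conftest import assemble_read, realize

MIX = {"clean": 30, "fail_L1": 10, "fail_mids": 10,
       "fail_primers": 10, "fail_L2": 5, "fail_quality": 5}


@pytest.fixture
def batch(config):
    fa, qa, truth = generate_clean_fixture(MIX, config, seed=7)
    return read_fasta_qual(fa, qa), truth


class TestAverageQuality:
    @pytest.mark.parametrize("quals,expected", [
        ([20, 20, 20], 20.0),
        ([0, 40], 20.0),
        ([10, 20, 40], 70 / 3),
    ])
    def test_examples(self, quals, expected):
        assert average_quality(quals) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_quality([])


class TestCleanRead:
    def test_intact_read_passes(self, config, rng):
        fw = realize(config.forward_primers[0], rng)
        rv = realize(config.reverse_primers[0], rng)
        gene = "".join(rng.choice(list("ACGT"), size=200))
        out = clean_read(assemble_read(config, 1, 2, fw, rv, gene), config)
        assert out.status == "pass"
        assert out.sample == "s1"
        assert out.gene.bases == gene

    def test_overlong_read_fails_l1_before_anything(self, config):
        from conftest import make_read
        out = clean_read(make_read("r", "TC" * 250), config)
        assert out.status == "fail_L1"

    def test_destroyed_primer_fails_primers(self, config, rng):
        rv = realize(config.reverse_primers[0], rng)
        gene = "".join(rng.choice(list("ACGT"), size=200))
        read = assemble_read(config, 1, 2, "TC" * 10, rv, gene)
        assert clean_read(read, config).status == "fail_primers"

    def test_unknown_tag_combination_fails_mids(self, config, rng):
        fw = realize(config.forward_primers[0], rng)
        rv = realize(config.reverse_primers[0], rng)
        gene = "".join(rng.choice(list("ACGT"), size=200))
        # tags 7 and 8 carry no sample in the default table
        read = assemble_read(config, 7, 8, fw, rv, gene)
        assert clean_read(read, config).status == "fail_mids"

    def test_boundary_quality_fails_strictly(self, config, rng):
        fw = realize(config.forward_primers[0], rng)
        rv = realize(config.reverse_primers[0], rng)
        gene = "".join(rng.choice(list("ACGT"), size=200))
        read = assemble_read(config, 1, 2, fw, rv, gene,
                             qual=int(config.quality_threshold))
        assert clean_read(read, config).status == "fail_quality"

    def test_sense_normalization(self, config, rng):
        fw = realize(config.forward_primers[0], rng)
        rv = realize(config.reverse_primers[0], rng)
        gene = "".join(rng.choice(list("ACGT"), size=200))
        fwd = clean_read(assemble_read(config, 1, 2, fw, rv, gene), config)
        flp = clean_read(assemble_read(config, 1, 2, fw, rv, gene, flipped=True), config)
        assert fwd.status == flp.status == "pass"
        assert fwd.gene.bases == flp.gene.bases == gene
        assert (fwd.original_orientation, flp.original_orientation) == ("sense", "antisense")

    def test_no_mid_mode_skips_tag_stage(self, config, rng):
        cfg = replace(config, mids=[], min_mid_len=5,
                      sample_table={(0, 0): "only"})
        fw = realize(cfg.forward_primers[0], rng)
        rv = realize(cfg.reverse_primers[0], rng)
        gene = "".join(rng.choice(list("ACGT"), size=200))
        read = assemble_read(cfg, 0, 0, fw, rv, gene)
        out = clean_read(read, cfg)
        assert out.status == "pass" and out.sample == "only"


class TestCleanDataset:
    def test_empty_input(self, config):
        stats, outcomes = clean_dataset([], config)
        assert stats.received == 0 and outcomes == []
        assert stats.per_sample["total"].sum() == 0

    def test_counts_match_generator_truth(self, config, batch):
        reads, truth = batch
        _, outcomes = clean_dataset(reads, config)
        by_id = {o.read_id: o for o in outcomes}
        for _, row in truth.iterrows():
            assert by_id[row.read_id].status == row.expected_status, row.read_id
        for _, row in truth[truth.expected_status == "pass"].iterrows():
            out = by_id[row.read_id]
            assert out.sample == row.expected_sample
            assert out.gene.bases == row.gene

    def test_order_invariance(self, config, batch):
        reads, _ = batch
        fwd, _ = clean_dataset(reads, config)
        rev, _ = clean_dataset(reads[::-1], config)
        import pandas.testing as pdt
        # counts are exact; the sample average tolerates summation order
        pdt.assert_frame_equal(fwd.per_sample, rev.per_sample,
                               check_exact=False, rtol=1e-12)
        assert (fwd.fail_l1, fwd.fail_mids) == (rev.fail_l1, rev.fail_mids)

    def test_conservation_and_file_routing(self, config, batch, tmp_path):
        reads, _ = batch
        stats, _ = clean_dataset(reads, config, outdir=str(tmp_path))
        n_failed = sum((tmp_path / f).read_text().count(">")
                       for f in ["FailedInFindMIDs.txt", "FailedInFindPrimers.txt",
                                 "FailedInCheckLength.txt", "FailedInQuality.txt"])
        n_kept = sum((tmp_path / f"{s}.txt").read_text().count(">")
                     for s in stats.per_sample["sample"])
        assert n_failed + n_kept == len(reads)
        # per-sample conservation
        ps = stats.per_sample
        assert (ps["total"] == ps[["failed_primers", "failed_length",
                                   "failed_quality", "remaining"]].sum(axis=1)).all()
        assert stats.received == stats.fail_l1 + stats.fail_mids + ps["total"].sum()

    def test_passed_genes_satisfy_bounds_post_hoc(self, config, batch):
        reads, _ = batch
        _, outcomes = clean_dataset(reads, config)
        for o in outcomes:
            if o.status == "pass":
                assert config.min_l2 <= len(o.gene) <= config.max_l2
                assert average_quality(o.gene.quals) > config.quality_threshold

    def test_widening_l2_never_converts_pass_to_fail(self, config, batch):
        reads, _ = batch
        wide = replace(config, min_l2=1, max_l2=config.max_l2 + 100)
        _, base = clean_dataset(reads, config)
        _, widened = clean_dataset(reads, wide)
        passed = {o.read_id for o in base if o.status == "pass"}
        passed_wide = {o.read_id for o in widened if o.status == "pass"}
        assert passed <= passed_wide

    def test_log_layout(self, config, batch, tmp_path):
        reads, _ = batch
        clean_dataset(reads, config, outdir=str(tmp_path))
        log = (tmp_path / "Log.txt").read_text().splitlines()
        assert log[0].split("\t") == LOG_COLUMNS
        assert any(line.startswith("Sequences received") for line in log)
        assert any(line.startswith("Antisense") for line in log)

    def test_sample_quals_refer_to_gene_only(self, config, batch, tmp_path):
        reads, _ = batch
        stats, outcomes = clean_dataset(reads, config, outdir=str(tmp_path))
        s = stats.per_sample["sample"][0]
        fa = (tmp_path / f"{s}.txt").read_text()
        qa = (tmp_path / f"{s}.qual").read_text()
        genes = read_fasta_qual(fa, qa)
        by_id = {o.read_id: o for o in outcomes}
        for g in genes:
            assert g == by_id[g.id].gene
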