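import numpy as np
import pytest

import mnpkit as mk
from mnpkit.errors import ContractError, DatabaseVersionError, FormatError

from conftest import TINY_VCF, make_profile, make_snp_table


class TestReadVcf:
    def test_preserves_records_and_samples(self, tiny_vcf):
        table = mk.read_vcf(tiny_vcf)
        assert len(table) == 3
        assert table.samples == ["s1"]
        recs = list(table.records())
        assert recs[0].genotypes == ((0, 1),)
        assert recs[1].alts == ("T", "A")      # multi-allelic kept unsplit
        assert recs[0].info == pytest.approx({"QD": 20.0, "FS": 1.5})
        # absent INFO keys are absent, not zero
        assert "FS" not in recs[1].info and "QD" not in recs[2].info

    def test_missing_genotype_is_first_class(self, tiny_vcf):
        table = mk.read_vcf(tiny_vcf)
        assert table.record(2).genotypes == (None,)
        assert table.record(2).genotypes[0] is not (0, 0)

    def test_unsorted_positions_rejected(self, tmp_path):
        bad = TINY_VCF.replace("chr1\t250", "chr1\t90")
        path = tmp_path / "bad.vcf"
        path.write_text(bad)
        with pytest.raises(FormatError, match="strictly increasing"):
            mk.read_vcf(path)

    def test_missing_gt_format_named(self, tmp_path):
        text = "\n".join(l for l in TINY_VCF.splitlines() if "ID=GT" not in l)
        text = text.replace("GT:DP", "DP").replace("0/1:", "").replace(
            "1/2:", "").replace("./.:", "")
        path = tmp_path / "nogt.vcf"
        path.write_text(text + "\n")
        with pytest.raises(ContractError, match="GT"):
            mk.read_vcf(path)

    def test_malformed_header(self, tmp_path):
        path = tmp_path / "junk.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(FormatError):
            mk.read_vcf(path)


class TestVcfRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_read_write_read_identity(self, tmp_path, seed):
        cfg = mk.SimConfig(chrom_lengths={"c1": 60_000, "c2": 40_000},
                           group_sizes={"w": 3, "g": 2}, snp_density=0.01,
                           n_hybrid_trios=0, seed=seed)
        _, table = mk.simulate_population(cfg)
        path = tmp_path / "rt.vcf"
        mk.write_vcf(table, path)
        again = mk.read_vcf(path)
        assert again == table
        path2 = tmp_path / "rt2.vcf"
        mk.write_vcf(again, path2)
        assert mk.read_vcf(path2) == again


class TestCountTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "counts.tsv"
        lines = ["strain\tmarker_id\thaplotype\tcount"]
        lines += ["\t".join(str(x) for x in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_grouped_by_marker(self, tmp_path):
        path = self._write(tmp_path, [("s", "m1", "ACG", 30), ("s", "m1", "TCG", 10)])
        ct = mk.read_count_table(path)
        assert set(ct.entries["m1"]) == {"ACG", "TCG"}
        assert sum(ct.entries["m1"].values()) == 40

    def test_duplicate_rows_summed(self, tmp_path):
        path = self._write(tmp_path, [("s", "m1", "ACG", 5), ("s", "m1", "ACG", 7)])
        assert mk.read_count_table(path).entries["m1"]["ACG"] == 12

    def test_inconsistent_haplotype_length(self, tmp_path):
        path = self._write(tmp_path, [("s", "m1", "ACG", 1), ("s", "m1", "AC", 1)])
        with pytest.raises(FormatError, match="length"):
            mk.read_count_table(path)

    def test_write_read_round_trip(self, tmp_path):
        ct = mk.CountTable(strain="x", entries={"m1": {"AA": 3, "AC": 9},
                                                "m2": {"G": 11}})
        path = tmp_path / "out.tsv"
        mk.write_count_table(ct, path)
        assert mk.read_count_table(path) == ct


def _random_db(seed):
    rng = np.random.default_rng(seed)
    n_markers = int(rng.integers(0, 8))
    markers = []
    for i in range(n_markers):
        k = int(rng.integers(2, 5))
        start = int(rng.integers(1, 10_000))
        offs = sorted(rng.choice(99, size=k, replace=False).tolist())
        markers.append(mk.MnpMarker(
            marker_id=f"mnp_{i:04d}", chrom="c1", start=start, end=start + 99,
            snp_positions=tuple(start + o for o in offs),
            pic=float(rng.uniform(0.5, 0.95)),
            allele_words={"R|R": 0.5, "1|1": 0.5}))
    profiles = []
    for j in range(int(rng.integers(0, 5))):
        calls = {}
        for m in markers:
            if rng.random() < 0.2:
                calls[m.marker_id] = None
            else:
                haps = ["".join(rng.choice(list("ACGT"), m.n_snps))
                        for _ in range(int(rng.integers(1, 3)))]
                calls[m.marker_id] = haps
        profiles.append(make_profile(f"strain{j}", calls))
    return mk.build_database(markers, profiles, meta={"seed": seed})


class TestDatabase:
    def test_empty_round_trip(self, tmp_path):
        db = mk.build_database([], [], meta={})
        path = tmp_path / "db.mnp"
        mk.save_database(db, path)
        assert mk.load_database(path) == db

    @pytest.mark.parametrize("seed", range(12))
    def test_round_trip_identity_property(self, tmp_path, seed):
        db = _random_db(seed)
        path = tmp_path / "db.mnp"
        mk.save_database(db, path)
        assert mk.load_database(path) == db

    def test_truncated_file_errors(self, tmp_path):
        db = _random_db(3)
        path = tmp_path / "db.mnp"
        mk.save_database(db, path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(FormatError):
            mk.load_database(path)

    def test_version_mismatch(self, tmp_path):
        path = tmp_path / "db.mnp"
        path.write_text('{"schema": "mnpkit.db/99", "meta": {}, '
                        '"markers": [], "profiles": {}}')
        with pytest.raises(DatabaseVersionError, match="mnpkit.db/99"):
            mk.load_database(path)


class TestWriters:
    def test_marker_table_row(self, tmp_path):
        m = mk.MnpMarker(marker_id="mnp_0001", chrom="chr1", start=100, end=199,
                         snp_positions=(100, 150, 190), pic=0.70)
        path = tmp_path / "markers.tsv"
        mk.write_marker_table([m], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[1].split("\t") == ["mnp_0001", "chr1", "100", "199", "3",
                                        "100,150,190", "0.7"]
        [back] = mk.read_marker_table(path)
        assert (back.chrom, back.start, back.end, back.snp_positions) == \
            ("chr1", 100, 199, (100, 150, 190))

    def test_two_leaf_newick(self, tmp_path):
        tree = mk.cluster_from_distances(np.array([[0.0, 1.0], [1.0, 0.0]]),
                                         ["A", "B"])
        path = tmp_path / "t.nwk"
        mk.write_newick(tree, path)
        assert path.read_text().strip() == "(A:0.5,B:0.5);"

    def test_symmetric_matrix_tsv(self, tmp_path):
        a, b = make_profile("a", {"m1": ["A"], "m2": ["C"]}), \
            make_profile("b", {"m1": ["A"], "m2": ["G"]})
        m = mk.gs_matrix(mk.MarkerDatabase(markers=[], profiles={"a": a, "b": b}))
        path = tmp_path / "gs.tsv"
        mk.write_matrix(m, path)
        frame = mk.read_matrix(path)
        assert frame.loc["a", "a"] == 100.00
        assert frame.loc["a", "b"] == frame.loc["b", "a"] == 50.00

    def test_profile_round_trip(self, tmp_path):
        p = make_profile("s1", {"m1": ["ACG", "TCG"], "m2": None})
        path = tmp_path / "p.tsv"
        mk.write_profile(p, path)
        back = mk.read_profile(path)
        assert back.strain == "s1"
        assert back.calls["m1"].haplotypes == frozenset({"ACG", "TCG"})
        assert back.calls["m2"].haplotypes is None
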