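"""Parsing, binning, capping, splitting, stratification, spectral file I/O."""

import numpy as np
import pytest

from espred import chemdata
from espred.chemdata import (EnergyNormalizer, InstrumentSetting, PairedCorpus,
                             Spectrum, bin_spectrum, cap_spectra_per_molecule,
                             parse_molecule, read_spectra, split_random,
                             split_realistic, stratify_by_formula)


SETTING = InstrumentSetting.make("[M+H]+", 0.5)


def _spec(bins: dict[int, float], mid: str | None = None, n_bins: int = 1000) -> Spectrum:
    v = np.zeros(n_bins)
    for b, x in bins.items():
        v[b] = x
    v /= np.linalg.norm(v)
    return Spectrum(v, precursor_mz=500.0, setting=SETTING, molecule_id=mid)


class TestParseMolecule:
    @pytest.mark.parametrize("smiles,formula,n_nodes,n_undirected", [
        ("CCO", "C2H6O", 3, 2),
        ("C", "CH4", 1, 0),
        ("c1ccccc1O", "C6H6O", 7, 7),
    ])
    def test_examples(self, smiles, formula, n_nodes, n_undirected):
        rec = parse_molecule(smiles)
        assert rec.formula == formula
        assert rec.graph.n_nodes == n_nodes
        assert rec.graph.n_edges == 2 * n_undirected

    def test_invalid_smiles_raises(self):
        with pytest.raises(chemdata.SmilesParseError, match="not_a_smiles"):
            parse_molecule("not_a_smiles")
        with pytest.raises(chemdata.SmilesParseError):
            parse_molecule("")

    def test_graph_edge_symmetry_and_bounds(self):
        g = parse_molecule("CC(=O)NC1=CC=C(O)C=C1").graph  # paracetamol
        pairs = {tuple(e) for e in g.edge_index}
        assert all((v, u) in pairs for u, v in pairs)
        assert g.edge_index.max() < g.n_nodes
        assert set(g.edge_types.tolist()) <= set(range(len(chemdata.BOND_TYPES)))

    def test_fingerprint_width_configurable(self):
        rec = parse_molecule("CCO", fp_bits=256)
        assert len(rec.fingerprint) == 256
        assert rec.fingerprint.sum() > 0


class TestBinSpectrum:
    def test_single_peak(self):
        s = bin_spectrum([(150.3, 10.0)], 200.0, SETTING)
        assert s.intensities[150] == pytest.approx(1.0)
        assert s.intensities.sum() == pytest.approx(1.0)

    def test_same_bin_merge(self):
        s = bin_spectrum([(150.3, 10.0), (150.9, 10.0)], 200.0, SETTING)
        assert np.count_nonzero(s.intensities) == 1
        assert s.intensities[150] == pytest.approx(1.0)

    def test_all_out_of_range_errors(self):
        with pytest.raises(ValueError, match="out of range"):
            bin_spectrum([(1000.5, 5.0)], 1000.0, SETTING)
        with pytest.raises(ValueError, match="empty"):
            bin_spectrum([], 100.0, SETTING)

    def test_conservation_before_normalization(self):
        rng = np.random.default_rng(3)
        peaks = [(float(m), float(i)) for m, i in
                 zip(rng.uniform(1, 1500, 50), rng.uniform(0.1, 5, 50))]
        in_range = sum(i for m, i in peaks if m < 1000)
        v = np.zeros(1000)
        for m, i in peaks:
            if m < 1000:
                v[int(np.floor(m))] += i
        s = bin_spectrum(peaks, 900.0, SETTING)
        # L2 normalization preserves direction: un-normalize and compare sums
        scale = in_range / s.intensities.sum()
        np.testing.assert_allclose(s.intensities * scale, v, atol=1e-9)

    def test_half_open_convention(self):
        s = bin_spectrum([(150.0, 1.0)], 200.0, SETTING)
        assert s.intensities[150] > 0 and s.intensities[149] == 0


def _toy_corpus(spectra_per_mol: dict[str, int]) -> PairedCorpus:
    mols = {}
    pairs = []
    smiles_pool = ["CCO", "CCC", "CCN", "CCCC", "CCOC", "CCCO", "CCCN",
                   "CC(C)O", "CC(C)C", "CCCCC", "CCCCO", "CCCCN"]
    for i, (mid, n) in enumerate(spectra_per_mol.items()):
        mols[mid] = parse_molecule(smiles_pool[i % len(smiles_pool)], mol_id=mid, fp_bits=64)
        for j in range(n):
            pairs.append((mid, _spec({10 + j: 1.0, 50: 0.5}, mid)))
    return PairedCorpus(molecules=mols, pairs=pairs)


class TestCapSpectra:
    def test_above_cap_downsampled(self):
        corpus = _toy_corpus({"a": 12, "b": 2})
        capped = cap_spectra_per_molecule(corpus, cap=5, seed=0)
        counts = {}
        for mid, _ in capped.pairs:
            counts[mid] = counts.get(mid, 0) + 1
        assert counts == {"a": 5, "b": 2}

    def test_below_cap_unchanged(self):
        corpus = _toy_corpus({"a": 3})
        capped = cap_spectra_per_molecule(corpus, cap=5, seed=1)
        assert [s for _, s in capped.pairs] == [s for _, s in corpus.pairs]

    def test_deterministic(self):
        corpus = _toy_corpus({"a": 9, "b": 7, "c": 2})
        one = cap_spectra_per_molecule(corpus, cap=5, seed=42)
        two = cap_spectra_per_molecule(corpus, cap=5, seed=42)
        for (m1, s1), (m2, s2) in zip(one.pairs, two.pairs):
            assert m1 == m2
            np.testing.assert_array_equal(s1.intensities, s2.intensities)


class TestSplits:
    def test_random_split_ratios_and_partition(self):
        corpus = _toy_corpus({f"m{i}": 1 for i in range(100)})
        split = split_random(corpus, seed=0)
        labels = list(split.splits.values())
        assert labels.count("train") == 80
        assert labels.count("val") == 10
        assert labels.count("test") == 10
        assert set(split.splits) == set(corpus.molecules)

    def test_random_split_deterministic(self):
        corpus = _toy_corpus({f"m{i}": 1 for i in range(30)})
        assert split_random(corpus, seed=5).splits == split_random(corpus, seed=5).splits

    def test_spectra_follow_molecule_split(self):
        corpus = _toy_corpus({f"m{i}": 3 for i in range(12)})
        split = split_random(corpus, seed=1)
        for mid, _ in split.pairs:
            assert split.splits[mid] in ("train", "val", "test")

    def test_too_few_molecules(self):
        with pytest.raises(ValueError):
            split_random(_toy_corpus({"a": 1, "b": 1}), seed=0)


class TestRealisticSplit:
    def test_two_families_separate(self):
        """Two chemically distinct families end up in distinct clusters,
        matching a direct average-linkage oracle on raw MACCS distances."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist
        from espred import synthetic_data

        fam_a = synthetic_data.enumerate_isomers("C8H18O2", 10, seed=0)
        fam_b = synthetic_data.enumerate_isomers("C5H14N2", 10, seed=0)
        mols = {}
        pairs = []
        truth = {}
        for fam, smis in (("A", fam_a), ("B", fam_b)):
            for i, smi in enumerate(smis):
                rec = parse_molecule(smi, mol_id=f"{fam}{i}", fp_bits=64)
                mols[rec.id] = rec
                truth[rec.id] = fam
                pairs.append((rec.id, _spec({20: 1.0}, rec.id)))
        corpus = PairedCorpus(molecules=mols, pairs=pairs)

        # oracle: UPGMA directly on MACCS jaccard distances
        mids = sorted(mols)
        X = np.array([mols[m].maccs for m in mids], dtype=bool)
        lab = fcluster(linkage(pdist(X, metric="jaccard"), method="average"),
                       t=2, criterion="maxclust")
        oracle_groups = {m: int(l) for m, l in zip(mids, lab)}
        assert len({oracle_groups[m] for m in mids if truth[m] == "A"}) == 1
        assert len({oracle_groups[m] for m in mids if truth[m] == "B"}) == 1

        split = split_realistic(corpus, n_clusters=2, n_train_clusters=1, seed=0)
        for fam in ("A", "B"):
            fam_clusters = {split.clusters[m] for m in mids if truth[m] == fam}
            assert len(fam_clusters) == 1
        assert len({split.clusters[m] for m in mids}) == 2

    def test_partition_property(self, small_corpus):
        split = split_realistic(small_corpus, n_clusters=5, n_train_clusters=3, seed=0)
        assert set(split.splits) == set(small_corpus.molecules)
        assert set(split.clusters) == set(small_corpus.molecules)
        assert set(split.splits.values()) == {"train", "test"}

    def test_largest_clusters_go_to_train(self, small_corpus):
        split = split_realistic(small_corpus, n_clusters=5, n_train_clusters=3, seed=0)
        sizes = {}
        for mid, c in split.clusters.items():
            sizes.setdefault(c, []).append(split.splits[mid])
        # size ties broken by ascending cluster label, as documented
        cluster_order = sorted(((-len(v), c) for c, v in sizes.items()))
        train_clusters = {c for c, v in sizes.items() if v[0] == "train"}
        assert train_clusters == {c for _, c in cluster_order[:3]}


class TestStratify:
    def test_isomer_grouping(self):
        mols = {
            "g1": parse_molecule("OCC(O)C(O)C(O)C(O)C=O", mol_id="g1", fp_bits=64),
            "g2": parse_molecule("OCC1OC(O)C(O)C(O)C1O", mol_id="g2", fp_bits=64),
            "x1": parse_molecule("OCC(O)C(O)C(O)C=O", mol_id="x1", fp_bits=64),
        }
        corpus = PairedCorpus(molecules=mols, pairs=[])
        strata = stratify_by_formula(corpus)
        assert sorted(map(len, strata.values())) == [1, 2]
        assert sorted(strata["C6H12O6"]) == ["g1", "g2"]

    def test_union_is_corpus(self, small_corpus):
        strata = stratify_by_formula(small_corpus)
        all_ids = sorted(mid for mids in strata.values() for mid in mids)
        assert all_ids == sorted(small_corpus.molecules)

    def test_split_restriction(self, small_corpus):
        strata = stratify_by_formula(small_corpus, split="train")
        for mids in strata.values():
            for mid in mids:
                assert small_corpus.splits[mid] == "train"


MGF_FIXTURE = """BEGIN IONS
TITLE=q0
PEPMASS=180.10
CHARGE=1+
ADDUCT=[M+H]+
COLLISION_ENERGY=20
57.2 100.0
85.1 40.0
END IONS

BEGIN IONS
TITLE=q1
PEPMASS=104.10
CHARGE=1+
ADDUCT=[M+H]+
COLLISION_ENERGY=40
45.0 10.0
END IONS
"""

MSP_FIXTURE = """Name: demo
PRECURSORMZ: 180.1
PRECURSORTYPE: [M+H]+
Collision_energy: 35
Num Peaks: 2
57.2 100.0
85.1 40.0
"""


class TestReadSpectra:
    def test_mgf_roundtrip(self, tmp_path):
        p = tmp_path / "two.mgf"
        p.write_text(MGF_FIXTURE)
        records = read_spectra(p, "MGF")
        assert len(records) == 2
        peaks0, meta0 = records[0]
        assert len(peaks0) == 2
        assert meta0["precursor_type"] == "[M+H]+"
        assert meta0["precursor_mz"] == pytest.approx(180.10)

    def test_msp_energy_normalized(self, tmp_path):
        p = tmp_path / "one.msp"
        p.write_text(MSP_FIXTURE)
        norm = EnergyNormalizer.fit([10.0, 50.0])
        records = read_spectra(p, "MSP", energy_normalizer=norm)
        assert len(records) == 1
        ce = records[0][1]["collision_energy"]
        assert 0.0 <= ce <= 1.0
        assert ce == pytest.approx((35 - 10) / 40)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.mgf"
        p.write_text("")
        assert read_spectra(p, "MGF") == []

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "x.mgf"
        p.write_text(MGF_FIXTURE)
        with pytest.raises(ValueError, match="dialect"):
            read_spectra(p, "mzTab")


class TestEnergyNormalizer:
    def test_minmax_and_clipping(self):
        norm = EnergyNormalizer.fit([10.0, 20.0, 40.0])
        assert norm(10.0) == 0.0
        assert norm(40.0) == 1.0
        assert norm(100.0) == 1.0  # clipped at inference
        assert norm(25.0) == pytest.approx(0.5)

    def test_constant_corpus_all_zero(self):
        norm = EnergyNormalizer.fit([35.0, 35.0])
        assert norm(35.0) == 0.0


class TestCorpusBundle:
    def test_save_load_roundtrip(self, small_corpus, tmp_path):
        chemdata.save_corpus(small_corpus, tmp_path / "bundle",
                             config={"fp_bits": 512})
        back = chemdata.load_corpus(tmp_path / "bundle")
        assert set(back.molecules) == set(small_corpus.molecules)
        assert back.splits == small_corpus.splits
        assert len(back.pairs) == len(small_corpus.pairs)
        np.testing.assert_allclose(back.pairs[0][1].intensities,
                                   small_corpus.pairs[0][1].intensities, atol=1e-6)
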