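"""Reference clustering, profile building/calibration and module scanning."""

import numpy as np
import pytest

from genostream.io import ProteinSet
from genostream.profiles import (
    CalibrationError,
    ModuleDefinition,
    build_module_profiles,
    build_profile,
    calibrate,
    cluster_references,
    module_matrix,
    scan,
)
from genostream.simulate import (
    _default_aa_freqs,
    _random_protein,
    generate_protein_family,
)


@pytest.fixture(scope="module")
def family():
    members, decoys, truth = generate_protein_family(200, 5, 0.4, 200, seed=17)
    return members, decoys, truth


class TestClustering:
    def test_identical_sequences_merge(self):
        rng = np.random.default_rng(1)
        s = _random_protein(120, _default_aa_freqs(), rng)
        assert len(cluster_references([("a", s), ("b", s)])) == 1

    def test_distant_sequences_stay_apart(self):
        rng = np.random.default_rng(2)
        p = _default_aa_freqs()
        refs = [("a", _random_protein(120, p, rng)),
                ("b", _random_protein(120, p, rng))]
        assert len(cluster_references(refs)) == 2

    def test_planted_tight_family_plus_singletons(self):
        members, _, _ = generate_protein_family(150, 5, 0.03, 0, seed=4)
        rng = np.random.default_rng(5)
        p = _default_aa_freqs()
        refs = members + [(f"s{i}", _random_protein(150, p, rng))
                          for i in range(3)]
        clusters = cluster_references(refs, identity=90, coverage=90)
        assert len(clusters) == 4
        assert max(len(c) for c in clusters) == 5


class TestProfiles:
    def test_single_member_profile_beats_decoys(self, family):
        members, decoys, _ = family
        model = build_profile(members[:1], profile_id="p0", n_decoys=100,
                              seed=0)
        s_true = model.score_sequence(members[0][1])
        s_decoys = [model.score_sequence(d) for _, d in decoys[:50]]
        assert s_true > max(s_decoys)

    def test_two_identical_members_match_single_member_scores(self, family):
        members, _, _ = family
        twin = [("a", members[0][1]), ("b", members[0][1])]
        m1 = build_profile(members[:1], profile_id="p1", n_decoys=0)
        m2 = build_profile(twin, profile_id="p2", n_decoys=0)
        assert np.allclose(m1.scores, m2.scores)

    def test_held_out_member_scores_above_decoys(self, family):
        members, decoys, _ = family
        model = build_profile(members[:4], profile_id="p", n_decoys=300, seed=1)
        s5 = model.score_sequence(members[4][1])
        decoy_scores = [model.score_sequence(d) for _, d in decoys]
        assert s5 > np.quantile(decoy_scores, 0.99)
        assert model.evalue(s5, 500) < 1e-3

    def test_uncalibrated_profile_refuses_evalues(self, family):
        members, _, _ = family
        model = build_profile(members[:2], profile_id="p", n_decoys=0)
        with pytest.raises(CalibrationError):
            model.evalue(10.0, 100)
        with pytest.raises(ValueError):
            calibrate(model, [m[1] for m in members[:2]], n_decoys=0)


class TestScan:
    def test_members_detected_and_random_proteome_clean(self, family):
        members, _, _ = family
        model = build_profile(members, profile_id="p", n_decoys=300, seed=2)
        hits = scan(ProteinSet("M", members), [model], max_evalue=1e-3)
        assert set(hits.protein_id) == {m for m, _ in members}
        rng = np.random.default_rng(6)
        p = _default_aa_freqs()
        rand = ProteinSet("R", [(f"r{i}", _random_protein(200, p, rng))
                                for i in range(500)])
        assert len(scan(rand, [model], max_evalue=1e-3)) <= 1

    def test_uncalibrated_scan_refused(self, family):
        members, _, _ = family
        model = build_profile(members[:2], profile_id="p", n_decoys=0)
        with pytest.raises(CalibrationError):
            scan(ProteinSet("M", members), [model])


@pytest.fixture(scope="module")
def modules_and_profiles():
    mods = []
    for i in (1, 2, 3):
        members, _, _ = generate_protein_family(
            160, 4, 0.3, 0, seed=40 + i, family_id=f"M{i:02d}ref")
        mods.append(ModuleDefinition(f"M{i:02d}", f"M{i:02d}-module", members))
    profiles = build_module_profiles(mods, n_decoys=200, seed=7)
    return mods, profiles


class TestModuleMatrix:
    def test_seeded_genome_shows_exactly_planted_modules(self,
                                                         modules_and_profiles):
        mods, profiles = modules_and_profiles
        rng = np.random.default_rng(9)
        p = _default_aa_freqs()
        background = [(f"b{i}", _random_protein(180, p, rng))
                      for i in range(30)]
        planted = [("g1_m01", mods[0].references[0][1]),
                   ("g1_m03", mods[2].references[1][1])]
        proteome = ProteinSet("g1", background + planted)
        hits = scan(proteome, profiles, max_evalue=1e-3)
        mat = module_matrix({"g1": hits}, mods, profiles)
        assert mat.loc["g1"].to_dict() == {"M01": 1, "M02": 0, "M03": 1}

    def test_no_hits_gives_all_absent_row(self, modules_and_profiles):
        mods, profiles = modules_and_profiles
        rng = np.random.default_rng(10)
        p = _default_aa_freqs()
        proteome = ProteinSet("g0", [(f"b{i}", _random_protein(150, p, rng))
                                     for i in range(20)])
        hits = scan(proteome, profiles, max_evalue=1e-3)
        mat = module_matrix({"g0": hits}, mods, profiles)
        assert mat.loc["g0"].sum() <= 1  # expected 0; allow one chance hit

    def test_module_without_profiles_rejected(self, modules_and_profiles):
        mods, profiles = modules_and_profiles
        import pandas as pd

        extra = ModuleDefinition("M99", "M99-empty",
                                 [("x", "MKVLWAALLVTFLAG")])
        with pytest.raises(ValueError, match="M99"):
            module_matrix({"g": pd.DataFrame(columns=["profile_id",
                                                      "module_id",
                                                      "protein_id", "score",
                                                      "evalue"])},
                          mods + [extra], profiles)

    def test_determinism_same_inputs_same_matrix(self, modules_and_profiles):
        mods, _ = modules_and_profiles
        p1 = build_module_profiles(mods, n_decoys=100, seed=11)
        p2 = build_module_profiles(mods, n_decoys=100, seed=11)
        assert all(np.allclose(a.scores, b.scores)
                   and a.gumbel_loc == b.gumbel_loc for a, b in zip(p1, p2))
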