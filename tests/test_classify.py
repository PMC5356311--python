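import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peroxevo.alignment import SiteMap, SitePosition
from peroxevo.classify import (TYPE_TABLE, SiteRules, TypingError,
                               classify_catalytic_profile,
                               partition_ancestor_set)
from peroxevo.models import build_model
from peroxevo.reconstruct import (all_marginal_posteriors,
                                  most_probable_sequence)
from peroxevo.sampling import sample_ancestors
from peroxevo.simulate import make_peroxidase_like_fixture

RULES = SiteRules()
# toy alignment: columns 0..3 hold positions 37, 41, 183, 172
SITES = SiteMap("ref", [SitePosition("37", 37, 0), SitePosition("41", 41, 1),
                        SitePosition("183", 183, 2), SitePosition("172", 172, 3)])


def seq(p37, p41, p183, p172, tail="G" * 6):
    return p37 + p41 + p183 + p172 + tail


class TestProfileExamples:
    @pytest.mark.parametrize("residues,expected_type,expected_site", [
        (("E", "E", "D", "A"), "MnP", "typical"),          # CaPo/CaCD-like
        (("E", "E", "D", "W"), "VP", "typical"),           # AVP-like
        (("D", "E", "N", "W"), "LiP", "none"),             # ALiP-like
        (("E", "E", "R", "A"), "GP", "blocked"),           # CaPo-bis-like
        (("Q", "E", "D", "A"), "MnP-atypical", "atypical"),  # CaPo-tris-like
        (("Q", "E", "D", "W"), "VP-atypical", "atypical"),
    ])
    def test_peroxidase_types(self, residues, expected_type, expected_site):
        prof = classify_catalytic_profile(seq(*residues), SITES, RULES)
        assert prof.type_label == expected_type
        assert prof.mn_site == expected_site

    def test_exact_matching_distinguishes_glu_from_asp(self):
        # Asp37 is acidic but does not support Mn2+ oxidation: not an exact match
        prof = classify_catalytic_profile(seq("D", "E", "D", "A"), SITES, RULES)
        assert prof.exact_triad_matches == 2
        assert prof.mn_site == "atypical"

    def test_lysine_also_blocks(self):
        prof = classify_catalytic_profile(seq("E", "E", "K", "A"), SITES, RULES)
        assert prof.mn_site == "blocked" and prof.type_label == "GP"

    def test_gap_counts_as_mismatch_and_is_flagged(self):
        prof = classify_catalytic_profile(seq("E", "E", "-", "W"), SITES, RULES)
        assert prof.exact_triad_matches == 2
        assert prof.masked_positions == ["183"]

    def test_type_mapping_is_total(self):
        assert set(TYPE_TABLE) == {(m, t) for m in
                                   ("typical", "atypical", "blocked", "none")
                                   for t in (True, False)}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=6, max_size=6))
    def test_invariant_to_background_residues(self, tail):
        a = classify_catalytic_profile(seq("E", "E", "D", "W"), SITES, RULES)
        b = classify_catalytic_profile(seq("E", "E", "D", "W", tail), SITES, RULES)
        assert (a.type_label, a.mn_site) == (b.type_label, b.mn_site)


class TestPartition:
    def _aset(self, sequences):
        from peroxevo.reconstruct import PosteriorMatrix
        from peroxevo.sampling import AncestorSet
        from peroxevo.reconstruct import AncestralSequence
        mp = AncestralSequence("n", sequences[0], np.ones(len(sequences[0])), 1.0)
        return AncestorSet("n", mp, list(sequences), [0.0] * len(sequences),
                           [0.2] * len(sequences), [0.2], len(sequences), 0)

    def test_all_vp(self):
        aset = self._aset([seq("E", "E", "D", "W")] * 4)
        part = partition_ancestor_set(aset, SITES, RULES)
        assert part.type_fractions == {"VP": 1.0}
        assert part.subset_fractions == {"typical-triad": 1.0}

    def test_mixed_fractions(self):
        aset = self._aset([seq("E", "E", "D", "W"), seq("E", "E", "D", "A")])
        part = partition_ancestor_set(aset, SITES, RULES)
        assert part.type_fractions == {"MnP": 0.5, "VP": 0.5}

    def test_basic_residue_goes_to_blocked_subset(self):
        aset = self._aset([seq("E", "E", "D", "A"), seq("E", "E", "R", "A")])
        part = partition_ancestor_set(aset, SITES, RULES)
        assert part.subset_fractions["basic-blocked"] == 0.5
        assert sum(part.subset_fractions.values()) == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        aset = self._aset([seq("E", "E", "D", "W")])
        aset.samples = []
        with pytest.raises(TypingError):
            partition_ancestor_set(aset, SITES, RULES)


class TestOnReconstructions:
    def test_confident_reconstruction_types_match_truth(self):
        """When per-position posteriors are sharp, the reconstructed ancestor
        is typed exactly like the true (designed) ancestor."""
        model = build_model("WAG", alpha=1.0, K=4)
        checked = 0
        for rep in range(5):
            fam, rules, sitemap, expected = make_peroxidase_like_fixture(
                seed=300 + rep)
            posts = all_marginal_posteriors(fam.tree, fam.leaf_alignment(),
                                            model, nodes=list(expected))
            for name, want in expected.items():
                post = posts[name]
                cols = [sitemap.column(l) for l in rules.all_labels()]
                if min(post.probs[c].max() for c in cols) < 0.9:
                    continue
                mp = most_probable_sequence(post)
                prof = classify_catalytic_profile(mp.sequence, sitemap, rules)
                assert prof.type_label == want
                checked += 1
        assert checked >= 20  # the design keeps motif posteriors sharp

    def test_sampled_set_unanimous_when_motif_fixed(self):
        fam, rules, sitemap, expected = make_peroxidase_like_fixture(seed=17)
        model = build_model("WAG", alpha=1.0, K=4)
        posts = all_marginal_posteriors(fam.tree, fam.leaf_alignment(), model,
                                        nodes=["VP2"])
        # at theta = 0.5 a competing residue needs half the posterior of the
        # designed one to be drawn at all, so the motif stays invariant
        aset = sample_ancestors(posts["VP2"], 200, [0.5], seed=1)
        part = partition_ancestor_set(aset, sitemap, rules)
        assert part.type_fractions.get("VP", 0.0) == 1.0
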