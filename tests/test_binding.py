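"""P-matrix construction, top-k consensus voting and the grid search."""

import numpy as np
import pytest

import rxnbind as rb
from rxnbind.model import AttentionTensor
from rxnbind.tokenization import TokenizedReaction


def _fixture_layout():
    """Bare 6-token layout (r=2, m=3, p=1, no specials) for hand checks.

    Enzyme tokens cover residues [0,2), [2,5), [5,7).
    """
    return TokenizedReaction(
        tokens=(10, 11, 12, 13, 14, 15),
        r=2,
        m_enz=3,
        p=1,
        enzyme_offsets=((0, 2), (2, 5), (5, 7)),
        special_positions=(),
    )


# Row-stochastic 6x6 attention fixture (enzyme at positions 2..4).
A_FIXTURE = np.array(
    [
        [0.1, 0.2, 0.3, 0.2, 0.1, 0.1],
        [0.3, 0.1, 0.1, 0.2, 0.2, 0.1],
        [0.2, 0.2, 0.2, 0.1, 0.2, 0.1],
        [0.1, 0.1, 0.4, 0.2, 0.1, 0.1],
        [0.2, 0.3, 0.1, 0.1, 0.2, 0.1],
        [0.1, 0.1, 0.1, 0.3, 0.2, 0.2],
    ]
)

# Hand computation: P[i][j] = A[i, 2+j] + A[2+j, i]
P_EXPECTED = np.array(
    [
        [0.3 + 0.2, 0.2 + 0.1, 0.1 + 0.2],
        [0.1 + 0.2, 0.2 + 0.1, 0.2 + 0.3],
    ]
)


def _fixture_attention():
    return AttentionTensor(values=A_FIXTURE[None, None], layout=_fixture_layout())


class TestPMatrix:
    def test_hand_computed_cells(self):
        p = rb.build_p_matrix(_fixture_attention(), layer=0, head=0)
        assert p.values.shape == (2, 3)
        assert np.allclose(p.values, P_EXPECTED)

    def test_uniform_attention_gives_constant_two_over_l(self):
        layout = _fixture_layout()
        uniform = AttentionTensor(values=np.full((1, 1, 6, 6), 1 / 6), layout=layout)
        p = rb.build_p_matrix(uniform, 0, 0)
        assert np.allclose(p.values, 2 / 6)

    def test_specials_are_skipped(self, untrained_model, tiny_encoded):
        enz, _ = tiny_encoded
        enc = enz[0]
        att = rb.attention_forward(untrained_model, enc)
        p = rb.build_p_matrix(att, 0, 0)
        assert p.values.shape == (enc.r, enc.m_enz)
        assert p.values.min() >= 0 and p.values.max() <= 2

    def test_organic_reaction_rejected(self, untrained_model, tiny_encoded):
        _, org = tiny_encoded
        att = rb.attention_forward(untrained_model, org[0])
        with pytest.raises(ValueError, match="no enzyme region"):
            rb.build_p_matrix(att, 0, 0)

    def test_out_of_range_layer_head(self):
        with pytest.raises(IndexError):
            rb.build_p_matrix(_fixture_attention(), layer=1, head=0)


def _brute_force_topk(values: np.ndarray, k: int) -> set[int]:
    m = values.shape[1]
    out: set[int] = set()
    for row in values:
        ranked = sorted(range(m), key=lambda j: (-row[j], j))
        out.update(ranked[: min(k, m)])
    return out


class TestVoteTopK:
    def test_worked_example(self):
        p = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1]])
        assert rb.vote_topk(p, 1) == {0, 1}

    def test_k_clamps_to_all_enzyme_tokens(self):
        p = np.array([[0.5, 0.2, 0.3]])
        assert rb.vote_topk(p, 10) == {0, 1, 2}

    def test_tie_breaks_to_lower_index(self):
        assert rb.vote_topk(np.array([[0.5, 0.5, 0.0]]), 1) == {0}

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            shape = (int(rng.integers(1, 8)), int(rng.integers(1, 12)))
            # coarse grid of values provokes plenty of ties
            p = rng.integers(0, 4, size=shape) / 4.0
            k = int(rng.integers(1, 6))
            assert rb.vote_topk(p, k) == _brute_force_topk(p, k)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(1)
        p = rng.random((5, 9))
        prev: set[int] = set()
        for k in range(1, 10):
            cur = rb.vote_topk(p, k)
            assert prev <= cur
            prev = cur

    def test_k_validation(self):
        with pytest.raises(ValueError):
            rb.vote_topk(np.ones((1, 2)), 0)


class TestTokensToSegments:
    def test_adjacent_tokens_merge(self):
        segs = rb.tokens_to_segments({1, 2}, [(0, 5), (5, 9), (9, 14)])
        assert segs.segments == ((5, 14),)

    def test_empty_and_disjoint(self):
        assert rb.tokens_to_segments(set(), [(0, 3)]).segments == ()
        segs = rb.tokens_to_segments({0, 2}, [(0, 3), (3, 6), (6, 9)])
        assert segs.segments == ((0, 3), (6, 9))

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            rb.tokens_to_segments({3}, [(0, 3), (3, 6)])


class TestPredictBindingSite:
    def test_composition_on_hand_fixture(self):
        att = _fixture_attention()
        p = rb.build_p_matrix(att, 0, 0)
        tokens = rb.vote_topk(p, 1)
        segs = rb.tokens_to_segments(tokens, att.layout.enzyme_offsets)
        # rows select columns 0 (0.5) and 2 (0.5): residues [0,2) and [5,7)
        assert tokens == {0, 2}
        assert segs.segments == ((0, 2), (5, 7))

    def test_k_equal_m_covers_whole_sequence(self, untrained_model, tiny_encoder, tiny_corpus):
        records, _ = tiny_corpus
        rxn = records[0].reaction
        enc = tiny_encoder.encode_reaction(rxn)
        cfg = rb.MapperConfig(layer=0, head=0, k=enc.m_enz)
        pred = rb.predict_binding_site(untrained_model, tiny_encoder, rxn, cfg)
        assert pred.segments.segments == ((0, len(rxn.enzyme.value)),)

    def test_repeated_calls_identical(self, untrained_model, tiny_encoder, tiny_corpus):
        records, _ = tiny_corpus
        rxn = records[3].reaction
        cfg = rb.MapperConfig(layer=1, head=2, k=3)
        a = rb.predict_binding_site(untrained_model, tiny_encoder, rxn, cfg)
        b = rb.predict_binding_site(untrained_model, tiny_encoder, rxn, cfg)
        assert a == b

    def test_atoms_only_restricts_voting_rows(self, untrained_model, tiny_encoder, tiny_corpus):
        from rxnbind.binding import atom_token_rows

        records, _ = tiny_corpus
        # pick a record whose reactants contain non-atom tokens (e.g. "(" or "=")
        rec = next(
            r for r in records
            if any(ch in "()=12" for mol in r.reaction.reactants for ch in mol)
        )
        enc = tiny_encoder.encode_reaction(rec.reaction)
        rows = atom_token_rows(tiny_encoder, enc)
        assert rows.any() and not rows.all()
        cfg = rb.MapperConfig(layer=0, head=0, k=2)
        all_votes = rb.predict_binding_site(untrained_model, tiny_encoder, enc, cfg)
        atom_votes = rb.predict_binding_site(
            untrained_model, tiny_encoder, enc, cfg, atoms_only=True
        )
        # atom-only consensus votes over a subset of rows
        assert atom_votes.source_tokens <= all_votes.source_tokens

    def test_coverage_monotone_in_k(self, untrained_model, tiny_encoder, tiny_corpus):
        records, _ = tiny_corpus
        rxn = records[5].reaction
        lengths = []
        for k in (1, 2, 4, 8):
            pred = rb.predict_binding_site(
                untrained_model, tiny_encoder, rxn, rb.MapperConfig(0, 1, k)
            )
            lengths.append(pred.segments.total_length)
        assert lengths == sorted(lengths)


class TestGridSearch:
    def _eval_set(self, tiny_corpus, n=3):
        records, _ = tiny_corpus
        return [(r.reaction, r.truth) for r in records[:n]]

    def test_single_candidate_returned(self, untrained_model, tiny_encoder, tiny_corpus):
        best, table = rb.grid_search(
            untrained_model, tiny_encoder, self._eval_set(tiny_corpus), [1], [2], [3]
        )
        assert best == rb.MapperConfig(layer=1, head=2, k=3)
        assert len(table) == 1

    def test_argmax_matches_independent_reevaluation(
        self, untrained_model, tiny_encoder, tiny_corpus
    ):
        eval_set = self._eval_set(tiny_corpus)
        best, table = rb.grid_search(untrained_model, tiny_encoder, eval_set, ks=(1, 3))
        # independent exhaustive oracle via the public one-example pipeline
        oracle = {}
        for layer in range(untrained_model.config.layers):
            for head in range(untrained_model.config.heads):
                for k in (1, 3):
                    scores = []
                    for rxn, truth in eval_set:
                        pred = rb.predict_binding_site(
                            untrained_model, tiny_encoder, rxn, rb.MapperConfig(layer, head, k)
                        )
                        scores.append(rb.overlap_score(pred.segments, truth))
                    oracle[(layer, head, k)] = float(np.mean(scores))
        best_score = max(oracle.values())
        expected = min(cfg for cfg, s in oracle.items() if s == best_score)
        assert (best.layer, best.head, best.k) == expected
        for _, row in table.iterrows():
            key = (int(row["layer"]), int(row["head"]), int(row["k"]))
            assert row["mean_overlap_score"] == pytest.approx(oracle[key])

    def test_deterministic_and_validates_ranges(self, untrained_model, tiny_encoder, tiny_corpus):
        eval_set = self._eval_set(tiny_corpus)
        a = rb.grid_search(untrained_model, tiny_encoder, eval_set, ks=(1,))
        b = rb.grid_search(untrained_model, tiny_encoder, eval_set, ks=(1,))
        assert a[0] == b[0] and a[1].equals(b[1])
        with pytest.raises(ValueError):
            rb.grid_search(untrained_model, tiny_encoder, [], ks=(1,))
        with pytest.raises(ValueError):
            rb.grid_search(untrained_model, tiny_encoder, eval_set, layers=[], ks=(1,))
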