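"""Amplification-bias simulator: limits, oracle arithmetic, competitor."""

import numpy as np
import pytest

from rflpdelta import (
    BiasModel,
    GelModel,
    MockCommunity,
    merge_bands,
    run_bias_scenarios,
    simulate_post_assembly,
    theoretical_count,
)

WINDOWED = GelModel(5, 50, 500, "strict")
OPEN = GelModel(5, None, None, "strict")


def _community(profiles, k, cid="c"):
    ids = sorted(profiles)[:k]
    return MockCommunity(cid, tuple(ids), k)


def test_unbiased_limit_recovers_theoretical(pool20_profiles):
    c = _community(pool20_profiles, 12)
    model = BiasModel(gamma=0.0, detect_threshold=0.0)
    for gel in (WINDOWED, OPEN):
        out = simulate_post_assembly(c, pool20_profiles, model, gel)
        theo = theoretical_count(c, pool20_profiles, gel)
        assert out.bands.bands == theo.bands


def test_pure_competitor_suppresses_all_bacterial_bands(pool20_profiles):
    c = _community(pool20_profiles, 8)
    model = BiasModel(gamma=1.0, competitor_fraction=1.0, detect_threshold=0.02)
    out = simulate_post_assembly(c, pool20_profiles, model, WINDOWED)
    assert out.n_bands == 0
    assert out.competitor_band_present
    assert out.competitor_mass == pytest.approx(1.0)


def test_winner_take_all_limit(pool20_profiles):
    c = _community(pool20_profiles, 5)
    winner = c.member_otu_ids[2]
    aff = {o: (1000.0 if o == winner else 1.0) for o in c.member_otu_ids}
    model = BiasModel(gamma=8.0, affinity=aff, detect_threshold=0.02)
    out = simulate_post_assembly(c, pool20_profiles, model, WINDOWED)
    winner_bands = merge_bands(pool20_profiles[winner].fragments, WINDOWED)
    # only bands carrying the preferred OTU remain visible (band anchors may
    # shift to co-migrating fragments of suppressed members)
    assert out.n_bands == winner_bands.n_bands
    assert all(winner in out.bands.contributing(i) for i in range(out.n_bands))
    assert out.per_otu_amplified_mass[winner] == pytest.approx(1.0, abs=1e-6)


def test_mass_formula_matches_independent_arithmetic(pool20_profiles):
    """Recompute the amplified-mass formula and band visibility with a
    separate numpy script and compare the observed band count."""
    c = _community(pool20_profiles, 15)
    model = BiasModel(gamma=2.0, detect_threshold=0.02, seed=99)
    out = simulate_post_assembly(c, pool20_profiles, model, WINDOWED)

    w = np.array([model.affinity_of(o) for o in c.member_otu_ids])
    conc = np.full(len(w), 1.0 / len(w))
    a = (w * conc) ** 2.0
    mass = dict(zip(c.member_otu_ids, a / a.sum()))
    tagged = sorted(
        (f, o)
        for o in c.member_otu_ids
        for f in pool20_profiles[o].fragments
        if 50 <= f <= 500
    )
    visible = 0
    i = 0
    while i < len(tagged):
        anchor = tagged[i][0]
        band_mass = 0.0
        while i < len(tagged) and tagged[i][0] - anchor < 5:
            band_mass += mass[tagged[i][1]]
            i += 1
        visible += band_mass >= 0.02
    assert out.n_bands == visible
    assert sum(out.per_otu_amplified_mass.values()) == pytest.approx(1.0)
    for o in c.member_otu_ids:
        assert out.per_otu_amplified_mass[o] == pytest.approx(mass[o])


def test_bacterial_bands_monotone_in_competitor_fraction(pool20_profiles):
    c = _community(pool20_profiles, 10)
    aff = {o: BiasModel(seed=5).affinity_of(o) for o in c.member_otu_ids}
    counts = []
    for f in np.linspace(0, 1, 11):
        model = BiasModel(
            gamma=1.0, affinity=aff, competitor_fraction=float(f),
            competitor_affinity=50.0, detect_threshold=0.02,
        )
        counts.append(
            simulate_post_assembly(c, pool20_profiles, model, WINDOWED).n_bands
        )
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_scenario_sweep_consistency(pool20_profiles):
    c = _community(pool20_profiles, 6)
    model = BiasModel(gamma=1.0, competitor_affinity=20.0, seed=4)
    table = run_bias_scenarios(
        [c], pool20_profiles, model, WINDOWED, cp_fractions=(0.0, 0.35, 0.65, 1.0)
    )
    assert len(table) == 4
    at = table.set_index("cp_fraction")
    # 0% control equals a plain simulation without competitor
    plain = simulate_post_assembly(c, pool20_profiles, model, WINDOWED)
    assert at.loc[0.0, "n_bands_observed"] == plain.n_bands
    assert not at.loc[0.0, "competitor_band_present"]
    assert at.loc[1.0, "n_bands_observed"] == 0
    assert at.loc[1.0, "competitor_band_present"]
    # intermediate fractions with a strong competitor suppress bacteria
    assert at.loc[0.65, "n_bands_observed"] <= at.loc[0.0, "n_bands_observed"]


def test_cyclewise_mode_runs_and_biases(pool20_profiles):
    c = _community(pool20_profiles, 8)
    model = BiasModel(mode="cyclewise", n_cycles=30, detect_threshold=0.02, seed=2)
    out = simulate_post_assembly(c, pool20_profiles, model, WINDOWED)
    theo = theoretical_count(c, pool20_profiles, WINDOWED)
    assert 0 < out.n_bands <= theo.n_bands


def test_observed_never_exceeds_theoretical(pool20_profiles):
    for seed in range(10):
        c = _community(pool20_profiles, 12, cid=f"c{seed}")
        model = BiasModel(seed=seed)
        out = simulate_post_assembly(c, pool20_profiles, model, WINDOWED)
        theo = theoretical_count(c, pool20_profiles, WINDOWED)
        assert out.n_bands <= theo.n_bands
        assert set(out.bands.bands) <= set(theo.bands)


def test_band_turnover_across_nested_sizes(pool20_profiles):
    """Visible band sets can change composition while counts stay flat."""
    ids = sorted(pool20_profiles)
    model = BiasModel(seed=7)
    sets = []
    for k in (5, 10, 15, 20):
        c = MockCommunity(f"n{k}", tuple(ids[:k]), k)
        sets.append(
            frozenset(simulate_post_assembly(c, pool20_profiles, model, WINDOWED).bands.bands)
        )
    assert any(a != b for a, b in zip(sets, sets[1:]))
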