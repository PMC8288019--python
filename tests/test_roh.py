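"""ROH callers, run merging, length spectrum, method comparison."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscape import (FilterPolicy, compare_methods, length_spectrum,
                      merge_runs, scan_roh, thin_depth, thin_variants,
                      window_het_counts, window_roh)
from rohscape.heterozygosity import het_sites


def _windows(counts, scaffold="s", window=100_000):
    starts = np.arange(len(counts)) * window
    return pd.DataFrame({"scaffold": scaffold, "start": starts,
                         "end": starts + window, "het_count": counts})


def test_window_roh_labels_and_f():
    lab = window_roh(_windows([0, 2, 0, 1]))
    assert list(lab.windows["roh"]) == [True, False, True, False]
    assert lab.f_roh == 0.5
    assert window_roh(_windows([0, 0, 0])).f_roh == 1.0
    with pytest.raises(ValueError):
        window_roh(_windows([]))


def test_window_roh_f_matches_brute_force_recount(small_genome):
    sim, _ = small_genome
    hets = het_sites(sim.variants)
    w = window_het_counts(hets, sim.scaffold_table)
    lab = window_roh(w)
    # oracle: recount every window directly from the site list
    n_roh = 0
    for row in w.itertuples():
        pos = hets.loc[hets["scaffold"] == row.scaffold, "pos"].to_numpy()
        n = ((pos >= row.start) & (pos < row.end)).sum()
        n_roh += int(n == 0)
    assert lab.f_roh == n_roh / len(w)


def test_merge_runs_examples_and_conservation():
    lab = window_roh(_windows([0, 0, 5, 0]))
    runs = merge_runs(lab)
    assert list(runs["length"]) == [200_000, 100_000]
    none = merge_runs(window_roh(_windows([3, 2])))
    assert len(none) == 0


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 3), min_size=1, max_size=60))
def test_merge_runs_conserves_total_length(counts):
    lab = window_roh(_windows(counts))
    runs = merge_runs(lab)
    assert runs["length"].sum() == int(lab.windows["roh"].sum()) * 100_000


def test_scan_roh_fully_homozygous_scaffold():
    pos = np.sort(np.random.default_rng(0).choice(300_000, 300,
                                                  replace=False))
    calls = pd.DataFrame({"scaffold": "s", "pos": pos, "is_het": False})
    runs = scan_roh(calls)
    assert len(runs) == 1
    assert runs.iloc[0]["start"] == pos[0]
    assert runs.iloc[0]["end"] == pos[-1] + 1
    assert runs.iloc[0]["method"] == "scan50"


def test_scan_roh_dense_heterozygotes_yield_no_runs():
    # every 5th call is het: any 50-site window holds 10 heterozygotes
    pos = np.arange(0, 500_000, 1000)
    calls = pd.DataFrame({"scaffold": "s", "pos": pos,
                          "is_het": np.arange(len(pos)) % 5 == 0})
    assert len(scan_roh(calls)) == 0


def test_scan_roh_skips_sparse_scaffold_with_warning():
    calls = pd.DataFrame({"scaffold": "s", "pos": np.arange(10) * 1000,
                          "is_het": False})
    with pytest.warns(UserWarning, match="fewer than 50"):
        runs = scan_roh(calls)
    assert len(runs) == 0


def test_scan_roh_recovers_planted_tract():
    """A 2-Mb autozygous tract inside a theta=200 background is recovered
    as one run overlapping at least 90% of the tract."""
    rng = np.random.default_rng(77)
    L = 6_000_000
    tract = (2_000_000, 4_000_000)
    het = rng.integers(0, L, size=int(200 * L / 1e6))
    het = het[(het < tract[0]) | (het >= tract[1])]
    hom = rng.integers(0, L, size=int(100 * L / 1e6))
    pos = np.concatenate([het, hom])
    is_het = np.concatenate([np.ones(len(het), bool),
                             np.zeros(len(hom), bool)])
    order = np.argsort(pos)
    calls = pd.DataFrame({"scaffold": "s", "pos": pos[order],
                          "is_het": is_het[order]})
    runs = scan_roh(calls)
    overlap = sum(max(0, min(r.end, tract[1]) - max(r.start, tract[0]))
                  for r in runs.itertuples())
    assert overlap >= 0.9 * (tract[1] - tract[0])


def test_length_spectrum_examples():
    runs = pd.DataFrame({"scaffold": ["s", "s"], "start": [0, 3_000_000],
                         "end": [500_000, 5_000_000],
                         "length": [500_000, 2_000_000]})
    spec = length_spectrum(runs, genome_length=10_000_000)
    assert spec.long_fraction == pytest.approx(0.2)
    assert spec.short_fraction == pytest.approx(0.05)
    assert (np.diff(spec.cumulative_fraction) >= 0).all()

    empty = length_spectrum(runs.iloc[:0], 10_000_000)
    assert empty.short_fraction == empty.long_fraction == 0.0


def test_length_spectrum_long_share_matches_mixture_expectation():
    from rohscape import ScaffoldDef, SimulatedGenomeSpec, \
        simulate_diploid_genome
    spec = SimulatedGenomeSpec(
        scaffolds=(ScaffoldDef("s1", 50_000_000),
                   ScaffoldDef("s2", 50_000_000)),
        theta=200.0, target_f=0.4, depth=None, seed=17)
    sim = simulate_diploid_genome(spec)
    runs = sim.truth.roh_intervals.assign(
        length=lambda d: d["end"] - d["start"])
    sp = length_spectrum(runs, 100_000_000)
    # expected long share of planted length: p_long*mean_long / mixture mean,
    # reduced because exponential(5 Mb) tracts below 1 Mb count as short
    assert 0.6 <= sp.long_fraction / (sp.long_fraction + sp.short_fraction) <= 0.97


def test_compare_methods_structure():
    f = pd.DataFrame({"window100k": [0.1, 0.4, 0.7],
                      "scan50": [0.1, 0.4, 0.7]},
                     index=["i1", "i2", "i3"])
    corr, means = compare_methods(f)
    assert corr.loc["window100k", "scan50"] == pytest.approx(1.0)
    assert means["window100k"] == pytest.approx(0.4)

    const = f.assign(scan50=0.5)
    corr2, _ = compare_methods(const)
    assert np.isnan(corr2.loc["window100k", "scan50"])

    with pytest.raises(ValueError):
        compare_methods(f.iloc[:2])


def test_thinning_never_decreases_window_f(small_genome):
    """Losing low-depth heterozygote calls can only empty windows."""
    sim, spec = small_genome
    pol = FilterPolicy()
    from rohscape import filter_genotypes
    full = filter_genotypes(sim.variants, pol, 30.0)
    w_full = window_het_counts(het_sites(full), sim.scaffold_table)
    f_full = window_roh(w_full).f_roh

    thin_recs = thin_variants(sim.variants, 0.4, seed=5)
    thin = filter_genotypes(thin_recs, pol,
                            thin_depth(sim.depth_track, 0.4, seed=6).mean_depth())
    w_thin = window_het_counts(het_sites(thin), sim.scaffold_table)
    f_thin = window_roh(w_thin).f_roh
    assert f_thin >= f_full
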