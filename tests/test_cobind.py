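"""Co-localization, composite profiles and architecture calls."""

import numpy as np
import pandas as pd
import pytest

from hifwnt.annotate import assign_peaks, bound_gene_set
from hifwnt.cobind import (CompositeProfile, anchor_positions, cobound_genes,
                           composite_profiles, detect_architecture,
                           genes_with_architecture, localization_density,
                           tss_anchor_positions)
from hifwnt.simulate import BindingSpec, simulate_annotation, simulate_peaks
from conftest import make_peaks, random_annotation, random_peaks

WINDOW = (-2000, 6000)


def _profile(factor, values, binwidth=10, halfwidth=None):
    values = np.asarray(values, dtype=float)
    halfwidth = halfwidth or binwidth * len(values) // 2
    edges = np.arange(-halfwidth, halfwidth + binwidth, binwidth, dtype=float)
    return CompositeProfile(factor, edges, values, n_anchors=1)


# ---------------------------------------------------------------------------
# co-bound genes
# ---------------------------------------------------------------------------

def test_gene_bound_by_one_factor_only_is_excluded(small_annotation):
    a = assign_peaks(make_peaks([("chr1", 9_900, 10_100, 10_000)], "A"),
                     small_annotation, WINDOW)
    b = assign_peaks(make_peaks([("chr1", 49_900, 50_100, 50_000)], "B"),
                     small_annotation, WINDOW)
    assert len(cobound_genes(a, b)) == 0


def test_identical_peak_sets_make_cobound_equal_bound(small_annotation):
    peaks = make_peaks([("chr1", 9_900, 10_100, 10_000),
                        ("chr2", 19_900, 20_100, 20_000)])
    a = assign_peaks(peaks, small_annotation, WINDOW)
    pairs = cobound_genes(a, a)
    assert set(pairs["gene_id"]) == bound_gene_set(a)
    assert (pairs["d_a"] == pairs["d_b"]).all()


@pytest.mark.parametrize("seed", range(3))
def test_cobound_equals_set_intersection_oracle(seed):
    rng = np.random.default_rng(seed)
    ann = random_annotation(rng, 150)
    a = assign_peaks(random_peaks(rng, 300, factor="A"), ann, WINDOW)
    b = assign_peaks(random_peaks(rng, 300, factor="B"), ann, WINDOW)
    pairs = cobound_genes(a, b)
    assert set(pairs["gene_id"]) == bound_gene_set(a) & bound_gene_set(b)


# ---------------------------------------------------------------------------
# joint density
# ---------------------------------------------------------------------------

def test_single_pair_occupies_one_cell():
    pairs = pd.DataFrame({"d_a": [150], "d_b": [-250]})
    grid = localization_density(pairs, binwidth=100, window=(-1000, 1000))
    assert grid.counts.sum() == 1
    i = np.searchsorted(grid.bin_edges_x, 150, side="right") - 1
    j = np.searchsorted(grid.bin_edges_y, -250, side="right") - 1
    assert grid.counts[i, j] == 1


def test_density_conserves_mass():
    rng = np.random.default_rng(1)
    pairs = pd.DataFrame({"d_a": rng.integers(-2000, 6000, 500),
                          "d_b": rng.integers(-2000, 6000, 500)})
    grid = localization_density(pairs, binwidth=500, window=WINDOW)
    assert grid.n_pairs == 500


def test_uniform_pairs_within_multinomial_envelope():
    rng = np.random.default_rng(2)
    n = 10_000
    pairs = pd.DataFrame({"d_a": rng.uniform(-1000, 1000, n),
                          "d_b": rng.uniform(-1000, 1000, n)})
    grid = localization_density(pairs, binwidth=500, window=(-1000, 1000))
    p = 1 / 16
    sigma = np.sqrt(n * p * (1 - p))
    assert (np.abs(grid.counts - n * p) <= 4 * sigma).all()


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def test_anchor_is_mean_of_summits_rounded_half_down():
    pairs = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                          "summit_a": [100, 500, 11],
                          "summit_b": [200, 500, 12]})
    anchors = anchor_positions(pairs)
    assert anchors.loc["g1"] == 150
    assert anchors.loc["g2"] == 500     # identical summits -> the summit
    assert anchors.loc["g3"] == 11      # 11.5 rounds half-down


@pytest.mark.parametrize("seed", [0, 1])
def test_anchor_matches_hand_computed_means(seed):
    rng = np.random.default_rng(seed)
    sa = rng.integers(0, 10_000, 50)
    sb = rng.integers(0, 10_000, 50)
    pairs = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)],
                          "summit_a": sa, "summit_b": sb})
    anchors = anchor_positions(pairs)
    for i in range(50):
        assert anchors.iloc[i] == int(np.floor((sa[i] + sb[i]) / 2))


# ---------------------------------------------------------------------------
# composite profiles
# ---------------------------------------------------------------------------

def _one_gene_setup(summit_offset=0):
    ann = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                        "tss": [10_000], "strand": ["+"]})
    peaks = make_peaks([("chr1", 9_800, 10_300, 10_000 + summit_offset)])
    anchors = pd.Series([10_000], index=["g1"], name="anchor")
    return ann, peaks, anchors


def test_single_summit_at_anchor_fills_zero_bin():
    ann, peaks, anchors = _one_gene_setup(0)
    prof = composite_profiles({"F": peaks}, anchors, ann, 100, 10)["F"]
    assert prof.values.sum() == 1.0
    zero_bin = np.searchsorted(prof.bin_edges, 0, side="right") - 1
    assert prof.values[zero_bin] == 1.0


def test_profile_translation_equivariance():
    """Shifting every summit by +k*binwidth shifts the profile by k bins."""
    ann, peaks, anchors = _one_gene_setup(0)
    k = 3
    shifted = peaks.assign(summit=peaks["summit"] + k * 10,
                           start=peaks["start"], end=peaks["end"] + k * 10)
    p0 = composite_profiles({"F": peaks}, anchors, ann, 100, 10)["F"].values
    p1 = composite_profiles({"F": shifted}, anchors, ann, 100, 10)["F"].values
    assert np.array_equal(np.roll(p0, k), p1)


def test_profile_mass_equals_summits_near_anchors():
    rng = np.random.default_rng(3)
    ann = random_annotation(rng, 40, span=500_000)
    peaks = random_peaks(rng, 400, span=500_000)
    anchors = tss_anchor_positions(ann["gene_id"], ann)
    halfwidth = 400
    profs = composite_profiles({"F": peaks}, anchors, ann, halfwidth, 10)
    mass = profs["F"].values.sum() * profs["F"].n_anchors
    oracle = 0
    for g in ann.itertuples(index=False):
        near = peaks[(peaks["chrom"] == g.chrom)
                     & (peaks["summit"] >= g.tss - halfwidth)
                     & (peaks["summit"] < g.tss + halfwidth)]
        # strand-oriented offsets flip the half-open edge for "-" genes
        if g.strand == "-":
            near = peaks[(peaks["chrom"] == g.chrom)
                         & (peaks["summit"] > g.tss - halfwidth)
                         & (peaks["summit"] <= g.tss + halfwidth)]
        oracle += len(near)
    assert mass == oracle


def test_halfwidth_must_be_multiple_of_binwidth(small_annotation):
    anchors = pd.Series([10_000], index=["gA"], name="anchor")
    with pytest.raises(ValueError, match="multiple"):
        composite_profiles({"F": make_peaks([])}, anchors, small_annotation,
                           105, 10)


def test_summit_mean_anchor_profiles_are_mirror_images():
    """With one representative summit per factor and pairwise-mean anchors,
    factor profiles are exact mirrors — the documented identifiability
    limit of that anchor choice."""
    chrom_sizes = {"chr1": 6_000_000}
    ann = simulate_annotation(2000, chrom_sizes, 2000, seed=11)
    genes = frozenset(ann["gene_id"])
    kw = dict(per_gene_binding_probability=1.0, background_peaks_per_mb=0.0)
    pa, _ = simulate_peaks(ann, BindingSpec("A", "h", genes,
                                            [(-40, 20, 1.0)], **kw),
                           chrom_sizes, seed=12)
    pb, _ = simulate_peaks(ann, BindingSpec("B", "h", genes,
                                            [(-40, 0, 2 / 3), (20, 40, 1 / 3)],
                                            **kw),
                           chrom_sizes, seed=13)
    pairs = cobound_genes(assign_peaks(pa, ann, WINDOW),
                          assign_peaks(pb, ann, WINDOW))
    anchors = anchor_positions(pairs)
    profs = composite_profiles({"A": pa, "B": pb}, anchors, ann, 400, 10)
    va, vb = profs["A"].values, profs["B"].values
    corr = np.corrcoef(va, vb[::-1])[0, 1]
    assert corr > 0.99


# ---------------------------------------------------------------------------
# architecture detection
# ---------------------------------------------------------------------------

def test_identical_profiles_have_no_specific_windows():
    v = [0, 0, 1, 1, 1, 0, 0, 0]
    call = detect_architecture({"A": _profile("A", v), "B": _profile("B", v)})
    assert call.specific_windows == {"A": [], "B": []}
    assert call.overlap_window == (-20.0, 10.0)
    assert call.overlap_width == 30.0


def test_disjoint_supports_give_empty_overlap():
    a = [1, 1, 0, 0, 0, 0, 0, 0]
    b = [0, 0, 0, 0, 1, 1, 0, 0]
    call = detect_architecture({"A": _profile("A", a), "B": _profile("B", b)})
    assert call.overlap_window is None and call.overlap_width == 0.0
    assert call.specific_width("A") == 20.0
    assert call.specific_width("B") == 20.0


def test_flat_profile_raises():
    with pytest.raises(ValueError, match="flat profile"):
        detect_architecture({"A": _profile("A", [0, 0, 0, 0]),
                             "B": _profile("B", [0, 1, 0, 0])})


def test_occupancy_threshold_is_per_factor_relative():
    a = [0, 10, 10, 4, 0, 0, 0, 0]   # active where >= 5 (50% of 10)
    b = [0, 0, 2, 2, 2, 0.9, 0, 0]   # active where >= 1 (50% of 2)
    call = detect_architecture({"A": _profile("A", a), "B": _profile("B", b)})
    assert call.overlap_window == (-20.0, -10.0)
    assert call.specific_windows["A"] == [(-30.0, -20.0)]
    assert call.specific_windows["B"] == [(-10.0, 10.0)]


def test_offset_estimate_is_occupancy_weighted_mean():
    a = [0, 0, 3, 2, 0, 0, 0, 0]   # active bins at centers -15, -5
    b = [0, 0, 0, 0, 2, 2, 0, 0]
    call = detect_architecture({"A": _profile("A", a), "B": _profile("B", b)})
    assert call.offset_estimate["A"] == pytest.approx(
        (3 * -15 + 2 * -5) / 5)
    assert call.offset_estimate["B"] == pytest.approx((5 + 15) / 2)


# ---------------------------------------------------------------------------
# architecture membership
# ---------------------------------------------------------------------------

def _membership_setup():
    ann = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
                        "tss": [10_000, 50_000], "strand": ["+", "+"]})
    call = detect_architecture({
        "A": _profile("A", [0, 0, 1, 1, 1, 1, 1, 0]),   # active [-20, 30)
        "B": _profile("B", [1, 1, 1, 1, 1, 0, 0, 0]),   # active [-40, 10)
    })
    # overlap [-20, 10); A-specific [10, 30); B-specific [-40, -20)
    anchors = pd.Series([10_000, 50_000], index=["g1", "g2"], name="anchor")
    return ann, call, anchors


def test_gene_with_summits_inside_windows_is_included():
    ann, call, anchors = _membership_setup()
    pairs = pd.DataFrame({"gene_id": ["g1", "g2"],
                          "summit_a": [10_015, 50_500],   # g2's A summit far out
                          "summit_b": [9_975, 49_990]})
    kept = genes_with_architecture(pairs, call, anchors, ann, "A", "B")
    assert kept == {"g1"}


@pytest.mark.parametrize("seed", range(3))
def test_membership_matches_direct_interval_oracle(seed):
    ann, call, _ = _membership_setup()
    rng = np.random.default_rng(seed)
    n = 60
    ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                        "chrom": "chr1",
                        "tss": np.arange(n) * 10_000 + 10_000,
                        "strand": [("+", "-")[int(s)]
                                   for s in rng.integers(0, 2, n)]})
    anchors = tss_anchor_positions(ann["gene_id"], ann)
    off_a = rng.integers(-60, 60, n)
    off_b = rng.integers(-60, 60, n)
    sign = np.where(ann["strand"] == "-", -1, 1)
    pairs = pd.DataFrame({"gene_id": ann["gene_id"],
                          "summit_a": ann["tss"] + sign * off_a,
                          "summit_b": ann["tss"] + sign * off_b})
    kept = genes_with_architecture(pairs, call, anchors, ann, "A", "B")
    wins_a = [(-20, 10), (10, 30)]
    wins_b = [(-20, 10), (-40, -20)]
    oracle = {g for g, oa, ob in zip(ann["gene_id"], off_a, off_b)
              if any(l <= oa < r for l, r in wins_a)
              and any(l <= ob < r for l, r in wins_b)}
    assert kept == oracle


def test_outputs_invariant_to_peak_file_ordering():
    rng = np.random.default_rng(9)
    ann = random_annotation(rng, 100)
    peaks = random_peaks(rng, 300)
    shuffled = peaks.sample(frac=1, random_state=1).reset_index(drop=True)
    a1 = assign_peaks(peaks, ann, WINDOW)
    a2 = assign_peaks(shuffled, ann, WINDOW)
    key = lambda df: sorted(zip(df["gene_id"], df["summit"], df["distance"]))
    assert key(a1) == key(a2)
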