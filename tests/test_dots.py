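"""Spot-caller correctness against a brute-force flood-fill oracle, dot
assignment, threshold optimization, and QC criteria."""

import numpy as np
import pytest

from bcdburst import (DotThresholds, PlateauNotFoundError, assign_dots,
                      detect_dots, optimize_threshold, qc_metrics)
from conftest import make_disc_nucleus, make_dot


def flood_fill_oracle(img, t_int, t_size, connectivity=2):
    """Independent BFS spot caller: clusters of pixels >= t_int with at
    least t_size members; returns a set of frozensets of pixel coords."""
    h, w = img.shape
    seen = np.zeros_like(img, dtype=bool)
    if connectivity == 2:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    clusters = set()
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0] or img[r0, c0] < t_int:
                continue
            stack, comp = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and not seen[rr, cc]
                            and img[rr, cc] >= t_int):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            if len(comp) >= t_size:
                clusters.add(frozenset(comp))
    return clusters


def as_pixel_sets(dots):
    return {frozenset(zip(d.pixels[0].tolist(), d.pixels[1].tolist()))
            for d in dots}


class TestDetectDots:
    def test_square_block_is_one_dot(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10:12, 10:12] = 40
        dots = detect_dots(img, DotThresholds(32, 4))
        assert len(dots) == 1
        assert dots[0].size == 4
        assert dots[0].raw_intensity == 160
        assert dots[0].centroid == (10.5, 10.5)

    def test_small_bright_cluster_fails_size_threshold(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[5, 5:8] = 200
        assert detect_dots(img, DotThresholds(32, 4)) == []

    @pytest.mark.parametrize("connectivity", [1, 2])
    @pytest.mark.parametrize("t_int,t_size", [(32, 4), (60, 2), (20, 6)])
    def test_matches_flood_fill_oracle(self, connectivity, t_int, t_size):
        rng = np.random.default_rng(hash((connectivity, t_int)) % 2 ** 31)
        for _ in range(12):
            img = np.zeros((64, 64), dtype=np.uint8)
            # sparse speckle plus a few blobs
            speckle = rng.random((64, 64)) < 0.05
            img[speckle] = rng.integers(10, 255, speckle.sum())
            for _ in range(4):
                r, c = rng.integers(4, 60, 2)
                img[r:r + 3, c:c + 3] = rng.integers(30, 255)
            got = as_pixel_sets(detect_dots(
                img, DotThresholds(t_int, t_size), connectivity=connectivity))
            want = flood_fill_oracle(img, t_int, t_size, connectivity)
            assert got == want

    def test_count_monotone_for_isolated_spots(self):
        # single-copy embryo: spots never share a nucleus, so no cluster
        # can split as the threshold rises and counts must not increase
        from bcdburst import EmbryoSpec, generate_embryo

        spec = EmbryoSpec(width=1024, height=256, copies_per_nucleus=1,
                          q_max=0.6, seed=5)
        image, _ = generate_embryo(spec)
        counts = [len(detect_dots(image.channels["intron"],
                                  DotThresholds(t, 4)))
                  for t in range(30, 80, 4)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_size_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        n = [len(detect_dots(img, DotThresholds(128, s))) for s in (1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(n, n[1:]))


class TestAssignDots:
    def test_centroid_in_nucleus(self):
        shape = (64, 64)
        nuc = [make_disc_nucleus(7, (20, 20), 8, shape),
               make_disc_nucleus(9, (20, 45), 8, shape)]
        dots = [make_dot((20, 20)), make_dot((40, 32))]
        assign_dots(dots, nuc, shape=shape)
        assert dots[0].nucleus_id == 7
        assert dots[1].nucleus_id is None
        assert nuc[0].dot_count == 1 and nuc[0].active
        assert nuc[1].dot_count == 0 and not nuc[1].active

    def test_synthetic_assignment_matches_truth(self, processed_small,
                                                small_embryo):
        _, truth = small_embryo
        res = processed_small
        planted = truth.nuclei[["center_row", "center_col"]].to_numpy()
        from scipy.spatial import cKDTree
        nuc_tree = cKDTree(planted)
        true_dot_tree = cKDTree(truth.dots[["row", "col"]].to_numpy())
        ok = tot = 0
        for d in res.dots:
            if d.nucleus_id is None:
                continue
            dist, j = true_dot_tree.query(d.centroid)
            if dist > 4:
                continue
            tot += 1
            # detected owner's centroid should be the planted owner
            rec = next(n for n in res.nuclei if n.id == d.nucleus_id)
            _, owner = nuc_tree.query(rec.centroid)
            if owner == truth.dots.nucleus.iloc[j]:
                ok += 1
        assert tot > 0 and ok / tot >= 0.95


class TestOptimizeThreshold:
    def test_plateau_on_synthetic_embryo(self, small_embryo):
        image, truth = small_embryo
        from bcdburst import annotate_nuclei, embryo_mask, estimate_axis, \
            segment_nuclei

        env = image.channels["envelope"]
        nuclei = segment_nuclei(env)
        axis = estimate_axis(embryo_mask(env), bcd=image.channels["bcd"])
        annotate_nuclei(nuclei, axis)
        thr, table = optimize_threshold(image.channels["intron"], nuclei)
        # chosen threshold separates haze ceiling from dot cores
        assert 20 <= thr.t_intensity <= 60
        assert (table.columns[:3] == ["t_intensity", "n_dots_total",
                                      "n_dots_nuclear"]).all()

    def test_strictly_decreasing_scan_raises_with_table(self):
        # one dot drops out of the high region at every threshold step, so
        # delta-rho decreases strictly and never plateaus
        shape = (64, 120)
        img = np.zeros(shape, dtype=np.uint8)
        hi = make_disc_nucleus(0, (32, 40), 12, shape)
        hi.x_over_L = 0.35
        lo = make_disc_nucleus(1, (32, 90), 12, shape)
        lo.x_over_L = 0.25
        offsets = [(dr, dc) for dr in range(-9, 10, 3)
                   for dc in range(-9, 10, 3)]
        for k, (dr, dc) in enumerate(offsets[:22]):
            img[32 + dr:34 + dr, 40 + dc:42 + dc] = 16 + 2 * k
        thr_range = range(14, 58, 2)
        with pytest.raises(PlateauNotFoundError) as err:
            optimize_threshold(img, [hi, lo], t_range=thr_range)
        assert err.value.scan_table is not None
        assert len(err.value.scan_table) == len(list(thr_range))


class TestQC:
    def test_no_cytoplasmic_dots_gives_zero_ratio(self):
        shape = (64, 64)
        nuc = [make_disc_nucleus(0, (32, 32), 8, shape)]
        nuc[0].x_over_L = 0.3
        dots = [make_dot((32, 32), nucleus_id=0)]
        nuc[0].dot_count = 1
        qc = qc_metrics(dots, nuc)
        assert qc.cytoplasm_to_nuclear_ratio == 0.0

    def test_fraction_with_more_than_two_dots(self):
        shape = (16, 16)
        nuclei = [make_disc_nucleus(i, (8, 8), 3, shape) for i in range(100)]
        for n in nuclei:
            n.x_over_L = 0.3
        nuclei[0].dot_count = 3
        nuclei[1].dot_count = 5
        qc = qc_metrics([], nuclei)
        assert qc.frac_nuclei_gt2 == pytest.approx(0.02)

    def test_empty_qc_window_reports_nan(self):
        shape = (16, 16)
        nuclei = [make_disc_nucleus(0, (8, 8), 3, shape)]
        nuclei[0].x_over_L = 0.2    # nothing in [0.55, 0.65]
        qc = qc_metrics([], nuclei)
        assert np.isnan(qc.nonexpression_dots_per_nucleus)

    def test_nonexpression_rate_zero_without_posterior_noise(self):
        from bcdburst import EmbryoSpec, generate_embryo
        from bcdburst.pipeline import process_embryo

        spec = EmbryoSpec(width=1024, height=256, posterior_domain=None,
                          hill_n=12.0, seed=8)   # razor-sharp response
        image, _ = generate_embryo(spec)
        res = process_embryo(image, thresholds=(32, 4))
        assert res.qc.nonexpression_dots_per_nucleus <= 0.05
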