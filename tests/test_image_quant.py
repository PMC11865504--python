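"""Segmentation and Hungarian tracking against rendered ground truth."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from actodrop.cell_sim import DropletState
from actodrop.image_quant import ImageStack, link_tracks, radius_and_volume, segment
from actodrop.synthetic_data import RenderOpts, render_stack

OPTS = RenderOpts(seed=7)
Z_MID = OPTS.n_slices * OPTS.z_step / 2.0


def droplet(i, x, y, R=0.8):
    return DropletState(id=i, x=x, y=y, z=Z_MID, R=R)


class TestRadiusVolume:
    @pytest.mark.parametrize(
        "area, R, V",
        [
            (math.pi, 1.0, 4.0 * math.pi / 3.0),
            (0.0, 0.0, 0.0),
            (2.0106, 0.8, 2.1447),
        ],
    )
    def test_spherical_conversion(self, area, R, V):
        r, v = radius_and_volume(area)
        assert r == pytest.approx(R, abs=1e-4)
        assert v == pytest.approx(V, abs=1e-3)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            radius_and_volume(-1.0)


class TestSegment:
    def test_single_disk_detected_with_accurate_area(self):
        stack, truth = render_stack([droplet(0, 6.0, 6.0, R=0.8)], OPTS)
        det = segment(stack)
        assert len(det) == 1
        assert det["area"].iloc[0] == pytest.approx(math.pi * 0.8 ** 2, rel=0.10)
        assert det["x"].iloc[0] == pytest.approx(6.0, abs=0.1)
        assert det["y"].iloc[0] == pytest.approx(6.0, abs=0.1)

    def test_small_droplets_all_detected(self):
        # droplets down to 3 px radius on a well-spaced grid: >= 95% found
        R = 3.0 * OPTS.pixel_size
        xs = np.linspace(2.0, 11.0, 4)
        drops = [droplet(i, x, y, R=R)
                 for i, (x, y) in enumerate(itertools.product(xs, xs))]
        det = segment(render_stack(drops, OPTS)[0])
        assert len(det) >= 0.95 * len(drops)

    def test_area_accuracy_at_study_scale(self):
        # thresholding after the σ=2 blur inflates areas of few-pixel
        # blobs; at the emulsion's typical droplet scale (R >= 6 px,
        # ~0.6 µm) measured areas are within 10% of truth
        for Rpx in (6.0, 8.0):
            R = Rpx * OPTS.pixel_size
            xs = np.linspace(2.0, 11.0, 3)
            drops = [droplet(i, x, y, R=R)
                     for i, (x, y) in enumerate(itertools.product(xs, xs))]
            det = segment(render_stack(drops, OPTS)[0])
            assert len(det) == len(drops)
            assert np.allclose(det["area"], math.pi * R ** 2, rtol=0.10)

    def test_tiny_blob_rejected_by_area_filter(self):
        # a 2-pixel blob (≈ 0.021 µm² at 103 nm/px) falls below the
        # 0.1 µm² threshold; a rendered disk in the same frame survives
        img = np.zeros((1, 64, 64))
        yy, xx = np.mgrid[:64, :64]
        img[0][np.hypot(yy - 20, xx - 20) <= 8.0] = 500.0
        img[0, 48, 48] = 500.0
        img[0, 48, 49] = 500.0
        det = segment(ImageStack(img[None], pixel_size=0.103), blur_sigma=0.0)
        assert len(det) == 1
        assert det["x"].iloc[0] == pytest.approx(20.5 * 0.103, abs=0.1)
        # and with the default blur the faint smeared speck is still absent
        det = segment(ImageStack(img[None], pixel_size=0.103))
        assert len(det) == 1

    def test_elongated_object_rejected_by_circularity(self):
        # a 2:1-aspect bar fails the 0.8-1 circularity window
        img = np.zeros((1, 64, 64))
        img[0, 28:36, 16:48] = 500.0  # 8 x 32 px bar
        det = segment(ImageStack(img[None], pixel_size=0.103))
        assert det.empty

    def test_constant_frame_yields_warning_and_no_detections(self):
        img = np.full((1, 1, 32, 32), 7.0)
        with pytest.warns(UserWarning, match="Otsu"):
            det = segment(ImageStack(img, pixel_size=0.103))
        assert det.empty

    def test_translation_equivariance(self):
        opts = RenderOpts(seed=7, read_noise=0.0, photon_scale=0.0, background=0.0)
        # noiseless: build one frame, then roll it by whole pixels
        stack, _ = render_stack([droplet(0, 4.0, 4.0), droplet(1, 9.0, 7.0)], OPTS)
        frame = stack.data[0]
        shifted = np.roll(frame, shift=(11, 5), axis=(1, 2))
        two = ImageStack(np.stack([frame, shifted]), pixel_size=OPTS.pixel_size)
        det = segment(two)
        a = det[det.frame == 0].sort_values("x")[["x", "y"]].to_numpy()
        b = det[det.frame == 1].sort_values("x")[["x", "y"]].to_numpy()
        shift_um = np.array([5 * OPTS.pixel_size, 11 * OPTS.pixel_size])
        assert np.allclose(b - a, shift_um, atol=0.02)


def _brute_force_links(prev, curr, max_dist):
    """Enumerate all injective partial matchings; maximize links, then
    minimize total distance.  Oracle for the Hungarian linker."""
    n, m = len(prev), len(curr)
    best = (0, 0.0, frozenset())
    idx = list(range(m)) + [None] * n
    for perm in set(itertools.permutations(idx, n)):
        links = []
        cost = 0.0
        ok = True
        for i, j in enumerate(perm):
            if j is None:
                continue
            d = math.dist(prev[i], curr[j])
            if d > max_dist:
                ok = False
                break
            links.append((i, j))
            cost += d
        if ok:
            key = (len(links), -cost)
            if key > (best[0], -best[1]):
                best = (len(links), cost, frozenset(links))
    return best


class TestLinkTracks:
    def _dets(self, frames_xy):
        rows = []
        for f, pts in enumerate(frames_xy):
            for x, y in pts:
                rows.append({"frame": f, "t": 9.0 * f, "x": x, "y": y,
                             "area": 2.0, "circularity": 1.0,
                             "radius": 0.8, "volume": 2.14})
        return pd.DataFrame(rows)

    def test_stationary_droplets_one_track_each(self):
        pts = [(1.0, 1.0), (5.0, 5.0), (9.0, 2.0)]
        tracks = link_tracks(self._dets([pts] * 10))
        assert tracks["track_id"].nunique() == 3
        assert (tracks.groupby("track_id")["frame"].count() == 10).all()

    def test_jump_beyond_max_distance_splits_track(self):
        frames = [[(1.0, 1.0)], [(2.5, 1.0)]]  # 1.5 µm > 1 µm
        tracks = link_tracks(self._dets(frames), max_distance=1.0)
        assert tracks["track_id"].nunique() == 2

    def test_gap_closing_up_to_three_frames(self):
        present = [[(3.0, 3.0)], [], [], [(3.1, 3.0)]]  # hidden 2 frames
        tracks = link_tracks(self._dets(present), max_gap=3)
        assert tracks["track_id"].nunique() == 1
        present = [[(3.0, 3.0)], [], [], [], [], [(3.1, 3.0)]]  # hidden 4
        tracks = link_tracks(self._dets(present), max_gap=3)
        assert tracks["track_id"].nunique() == 2

    def test_assignment_matches_brute_force(self, rng):
        # optimality on random frames with <= 6 detections
        for trial in range(10):
            n = int(rng.integers(2, 7))
            prev = rng.uniform(0.0, 4.0, size=(n, 2))
            curr = prev + rng.normal(0.0, 0.4, size=(n, 2))
            n_links, cost, links = _brute_force_links(
                [tuple(p) for p in prev], [tuple(c) for c in curr], 1.0)
            frames = [[tuple(p) for p in prev], [tuple(c) for c in curr]]
            tracks = link_tracks(self._dets(frames), max_distance=1.0)
            linked = tracks.groupby("track_id").filter(lambda g: len(g) == 2)
            got = set()
            got_cost = 0.0
            for _, g in linked.groupby("track_id"):
                g = g.sort_values("frame")
                i = int(np.argmin([math.dist((g.x.iloc[0], g.y.iloc[0]), p) for p in prev]))
                j = int(np.argmin([math.dist((g.x.iloc[1], g.y.iloc[1]), c) for c in curr]))
                got.add((i, j))
                got_cost += math.dist(tuple(prev[i]), tuple(curr[j]))
            assert len(got) == n_links
            assert got_cost == pytest.approx(cost, abs=1e-9)

    def test_roundtrip_identity_on_rendered_movie(self):
        # well-spaced droplets moving < 1 µm/frame: exact identity recovery
        n_frames, speed = 6, 0.4
        frames = [
            [droplet(i, 2.0 + 3.0 * i + speed * f, 3.0 + 2.0 * i) for i in range(3)]
            for f in range(n_frames)
        ]
        stack, truth = render_stack(frames, OPTS)
        tracks = link_tracks(segment(stack))
        assert tracks["track_id"].nunique() == 3
        assert (tracks.groupby("track_id")["frame"].count() == n_frames).all()
        # each track stays within 0.2 µm of one ground-truth trajectory
        for tid, g in tracks.groupby("track_id"):
            g = g.sort_values("frame")
            errs = []
            for i in range(3):
                gt = truth[truth.id == i].sort_values("frame")
                errs.append(np.hypot(g.x.to_numpy() - gt.x.to_numpy(),
                                     g.y.to_numpy() - gt.y.to_numpy()).max())
            assert min(errs) < 0.2
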