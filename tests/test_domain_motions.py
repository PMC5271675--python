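"""DCC computation and single-linkage domain clustering."""

import math

import numpy as np
import pytest

from dyncomp.domain_motions import (
    DCCMatrix,
    cluster_series,
    dcc,
    dcc_matrix,
    drop_zero_variance,
)
from dyncomp.exceptions import UndefinedCorrelationError, ValidationError
from dyncomp.synthetic import DomainBlockSpec, SyntheticSpec, generate_series_set
from helpers import make_series


def fsum_pearson(a, b):
    """Independent direct-summation Pearson oracle (math.fsum arithmetic)."""
    n = len(a)
    ma = math.fsum(a) / n
    mb = math.fsum(b) / n
    cov = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = math.fsum((x - ma) ** 2 for x in a)
    vb = math.fsum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def test_dcc_affine_and_sign_behavior():
    rng = np.random.default_rng(0)
    a = rng.normal(size=100)
    assert dcc(a, 2 * a + 3) == pytest.approx(1.0, abs=1e-12)
    assert dcc(a, -a) == pytest.approx(-1.0, abs=1e-12)
    b = rng.normal(size=100)
    r = dcc(a, b)
    assert dcc(a, 5.0 * b + 17.0) == pytest.approx(r, abs=1e-12)  # scale/offset invariant
    assert dcc(b, a) == pytest.approx(r, abs=1e-12)               # symmetric
    assert dcc(a, -b) == pytest.approx(-r, abs=1e-12)


def test_dcc_matches_direct_summation_oracle():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=20), rng.normal(size=20)
    assert dcc(a, b) == pytest.approx(fsum_pearson(a, b), abs=1e-12)


def test_zero_variance_series_rejected_and_droppable():
    flat = make_series(np.full(50, 7.0), idx=0)
    wavy = make_series(np.sin(np.arange(50.0)) + 7, idx=1)
    with pytest.raises(UndefinedCorrelationError):
        dcc(flat, wavy)
    kept, dropped = drop_zero_variance([flat, wavy])
    assert [s.series_id for s in kept] == [wavy.series_id]
    assert dropped == [flat.series_id]
    with pytest.raises(UndefinedCorrelationError):
        dcc_matrix([flat, wavy])


def test_dcc_matrix_identities():
    rng = np.random.default_rng(2)
    base = rng.normal(size=80)
    identical = [make_series(2.0 * base + 10.0, idx=i) for i in range(3)]
    m = dcc_matrix(identical)
    np.testing.assert_allclose(m.r, 1.0, atol=1e-12)

    mixed = [make_series(rng.normal(size=80) + 8, idx=i) for i in range(5)]
    m = dcc_matrix(mixed)
    np.testing.assert_array_equal(m.r, m.r.T)
    np.testing.assert_allclose(np.diag(m.r), 1.0)


def test_block_structure_from_generator():
    spec = SyntheticSpec(
        n_frames=1000, switches=(),
        blocks=(DomainBlockSpec("b", n_members=5, amplitude=4.0, noise_sigma=0.2),),
        n_background=5, seed=4,
    )
    ss = generate_series_set(spec)
    m = dcc_matrix(ss.series)
    block_ids = [s.series_id for s in ss.series if ss.labels[s.series_id] == "block:b"]
    noise_ids = [s.series_id for s in ss.series if ss.labels[s.series_id] == "background"]
    for i, a in enumerate(block_ids):
        for b in block_ids[i + 1:]:
            assert m.lookup(a, b) >= 0.95
        for b in noise_ids:
            assert abs(m.lookup(a, b)) <= 0.3


def test_cluster_all_perfectly_correlated():
    base = np.random.default_rng(5).normal(size=60)
    series = [make_series(base * (i + 1) + 20.0 + i, idx=i) for i in range(4)]
    comps = cluster_series(dcc_matrix(series), r_min=0.95)
    assert len(comps) == 1
    assert set(comps[0].member_series) == {s.series_id for s in series}
    assert comps[0].kind == "domain"


def test_two_planted_blocks_recovered_exactly():
    spec = SyntheticSpec(
        n_frames=1000, switches=(),
        blocks=(
            DomainBlockSpec("a", n_members=5, midpoint_frac=0.15, tau_frac=1 / 60),
            DomainBlockSpec("b", n_members=5, midpoint_frac=0.85, tau_frac=1 / 60),
        ),
        drift_wiggle_frac=0.02, seed=6,
    )
    ss = generate_series_set(spec)
    comps = cluster_series(dcc_matrix(ss.series), r_min=0.95)
    got = {frozenset(c.member_series) for c in comps}
    want = {
        frozenset(s.series_id for s in ss.series if ss.labels[s.series_id] == f"block:{name}")
        for name in ("a", "b")
    }
    assert got == want


def test_single_linkage_contract_every_member_has_close_neighbor():
    rng = np.random.default_rng(7)
    shared = rng.normal(size=300)
    series = [make_series(shared + rng.normal(0, s, 300) + 10, idx=i)
              for i, s in enumerate([0.05, 0.05, 0.08, 1.0, 2.0, 3.0])]
    m = dcc_matrix(series)
    r_min = 0.95
    for comp in cluster_series(m, r_min=r_min):
        for sid in comp.member_series:
            others = [o for o in comp.member_series if o != sid]
            assert max(m.lookup(sid, o) for o in others) >= r_min


def _threshold_components(r, r_min):
    """BFS connected components of the graph {(i, j): r_ij >= r_min} (oracle)."""
    n = r.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            stack.extend(j for j in range(n) if j != i and r[i, j] >= r_min and j not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def _random_structured_series(rng, n_series, n_frames=40):
    groups = rng.integers(0, 3, n_series)
    latents = rng.normal(size=(3, n_frames))
    out = []
    for i in range(n_series):
        noise = rng.uniform(0.005, 1.5)
        out.append(make_series(latents[groups[i]] + rng.normal(0, noise, n_frames) + 8, idx=i))
    return out


def test_single_linkage_equals_threshold_graph_components():
    # nearest-point/threshold duality: exact equality with the BFS oracle
    for seed in range(10):
        rng = np.random.default_rng(seed)
        series = _random_structured_series(rng, int(rng.integers(5, 30)))
        m = dcc_matrix(series)
        comps = cluster_series(m, r_min=0.95, min_cluster_size=1)
        got = {
            frozenset(m.index(sid) for sid in c.member_series) for c in comps
        }
        assert got == _threshold_components(m.r, 0.95)


def test_raising_r_min_only_refines_clusters():
    rng = np.random.default_rng(8)
    series = _random_structured_series(rng, 25)
    m = dcc_matrix(series)
    coarse = cluster_series(m, r_min=0.6, min_cluster_size=1)
    fine = cluster_series(m, r_min=0.9, min_cluster_size=1)
    coarse_of = {}
    for c in coarse:
        for sid in c.member_series:
            coarse_of[sid] = c.component_id
    for c in fine:  # every fine cluster fits inside one coarse cluster
        assert len({coarse_of[sid] for sid in c.member_series}) == 1


def test_invalid_r_min_rejected():
    series = [make_series(np.random.default_rng(9).normal(size=30) + 5, idx=i)
              for i in range(3)]
    with pytest.raises(ValidationError):
        cluster_series(dcc_matrix(series), r_min=1.5)
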