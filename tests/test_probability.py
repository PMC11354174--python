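"""Internal/external probability estimators, entropy, information amounts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogsys import (
    CognitionCondition,
    EventDistribution,
    EventLabeling,
    ObserverInfluenceError,
    UndefinedProbabilityError,
    World,
    audit_observer,
    entropy,
    external_p_cog,
    external_p_overall,
    identity_cognizer,
    info_amount,
    p_cog,
    p_cog_distribution,
    p_overall,
    umwelt_summary,
)
from cogsys.io import FixtureSpec, fixture_world


def naive_recount(states, labeling, event, cond=None, lag=1):
    """Independent brute-force scanner over a focal state sequence."""
    pairs = list(zip(states, states[1:]))
    labeled = [(i, labeling.label(a, b)) for i, (a, b) in enumerate(pairs)]
    if cond is None:
        labs = [l for _, l in labeled if l is not None]
        return sum(l == event for l in labs), len(labs)
    num = den = 0
    for i, (a, b) in enumerate(pairs):
        if (a, b) != cond:
            continue
        following = [l for j, l in labeled if j > i and l is not None]
        if len(following) < lag:
            continue
        den += 1
        num += following[lag - 1] == event
    return num, den


def test_p_cog_w2_hand_count(w2):
    t = w2.trajectory(("x", "p"), 3)
    lab = EventLabeling.by_successor("C1")
    r = p_cog(t, CognitionCondition("C1", "x", "x"), lab, "y")
    assert (r.value, r.numerator, r.denominator) == (1.0, 1, 1)


def test_p_cog_certainty_when_every_following_event_matches(w2):
    t = w2.trajectory(("x", "q"), 6)  # C1: x,y,y,y,... all events "y" after x->y
    lab = EventLabeling.by_successor("C1")
    r = p_cog(t, CognitionCondition("C1", "x", "y"), lab, "y")
    assert r.value == 1.0


def test_p_cog_zero_conditioning_events_is_undefined(w2):
    t = w2.trajectory(("x", "p"), 3)
    lab = EventLabeling.by_successor("C1")
    with pytest.raises(UndefinedProbabilityError, match="zero conditioning"):
        p_cog(t, CognitionCondition("C1", "y", "x"), lab, "y")
    # condition occurring only at the final transition is also undefined
    t2 = w2.trajectory(("x", "p"), 1)  # single transition x->x
    with pytest.raises(UndefinedProbabilityError):
        p_cog(t2, CognitionCondition("C1", "x", "x"), lab, "x")


def test_p_overall_w2_hand_count(w2):
    t = w2.trajectory(("x", "p"), 3)
    lab = EventLabeling.by_successor("C1")
    r = p_overall(t, lab, "y")
    assert (r.numerator, r.denominator) == (2, 3)


def test_p_overall_single_label_normalizes():
    lab = EventLabeling(focal="C1", default_label="e")
    w = World([identity_cognizer("C1", ["a"], 0)])
    t = w.trajectory(("a",), 4)
    assert p_overall(t, lab, "e").value == 1.0
    assert p_overall(t, lab, "other").value == 0.0


def test_law_of_total_counts(w2):
    t = w2.trajectory(("x", "p"), 12)
    lab = EventLabeling.by_successor("C2")
    cond = CognitionCondition("C2", "p", "p")
    dist = p_cog_distribution(t, cond, lab)
    total = sum(dist.support_counts)
    for ev in dist.labels:
        r = p_cog(t, cond, lab, ev)
        assert r.denominator == total
    assert sum(p_cog(t, cond, lab, ev).numerator for ev in dist.labels) == total


def test_oracle_recount_on_random_worlds():
    rng = np.random.default_rng(3)
    for _ in range(15):
        w = fixture_world(FixtureSpec(n_cognizers=2, n_states=3), int(rng.integers(2**31)))
        u0 = sorted(w.joint_states)[int(rng.integers(len(w.joint_states)))]
        t = w.trajectory(u0, 30)
        lab = EventLabeling.by_successor("C1")
        seq = t.component("C1")
        for ev in w.cognizers[0].states:
            r = p_overall(t, lab, ev)
            assert (r.numerator, r.denominator) == naive_recount(seq, lab, ev)
            for a in w.cognizers[0].states:
                for b in w.cognizers[0].states:
                    num, den = naive_recount(seq, lab, ev, cond=(a, b))
                    if den == 0:
                        continue
                    r = p_cog(t, CognitionCondition("C1", a, b), lab, ev)
                    assert (r.numerator, r.denominator) == (num, den)


def test_umwelt_summary_is_the_full_overall_distribution(w2):
    t = w2.trajectory(("x", "p"), 9)
    lab = EventLabeling.by_successor("C1")
    dist = umwelt_summary(t, lab)
    assert math.isclose(float(dist.probs.sum()), 1.0)
    for ev in dist.labels:
        assert math.isclose(dist.prob(ev), p_overall(t, lab, ev).value)


# -- external observers -----------------------------------------------------------


def _observed_w2():
    """W2 plus a blind (constant) observer and an influencing impostor."""
    f1 = {"xp": "x", "xq": "y", "yp": "y", "yq": "y"}
    f2 = {"xp": "q", "xq": "p", "yp": "p", "yq": "q"}
    c1 = lambda u: f1[u[0] + u[1]]
    c2 = lambda u: f2[u[0] + u[1]]
    from cogsys import Cognizer

    blind = Cognizer("O", ["o"], fn=lambda u: "o")
    w = World([Cognizer("C1", ["x", "y"], fn=c1), Cognizer("C2", ["p", "q"], fn=c2), blind])
    return w


def test_blind_observer_p_cog_equals_p_overall():
    w = _observed_w2()
    t = w.trajectory(("x", "p", "o"), 8)
    audit_observer(w, "O")
    lab = EventLabeling(focal="O", default_label="tick")
    r_cog = external_p_cog(w, t, CognitionCondition("O", "o", "o"), lab, "tick")
    r_all = external_p_overall(w, t, lab, "tick")
    assert r_cog.value == r_all.value == 1.0


def test_influential_observer_is_rejected():
    from cogsys import Cognizer

    c1 = Cognizer("C1", ["x", "y"], fn=lambda u: "x" if u[1] == "o1" else "y")
    obs = Cognizer("O", ["o1", "o2"], fn=lambda u: "o2")
    w = World([c1, obs])
    lab = EventLabeling(focal="O", default_label="tick")
    with pytest.raises(ObserverInfluenceError):
        external_p_overall(w, w.trajectory(("x", "o1"), 3), lab, "tick")


# -- entropy / information ----------------------------------------------------------


@pytest.mark.parametrize(
    "probs,expected",
    [
        ([0.5, 0.5], 1.0),
        ([1.0], 0.0),
        ([1.0, 0.0], 0.0),
        ([0.2, 0.3, 0.5], 1.4854752972273344),
        ([0.25] * 4, 2.0),
    ],
)
def test_entropy_closed_forms(probs, expected):
    assert math.isclose(entropy(probs), expected, abs_tol=1e-12)


def test_entropy_rejects_invalid_distributions():
    with pytest.raises(ValueError):
        entropy([0.5, 0.6])
    with pytest.raises(ValueError):
        entropy([-0.1, 1.1])


def test_entropy_of_event_distribution_bounded():
    d = EventDistribution(("a", "b", "c"), (1, 2, 7))
    assert 0.0 <= entropy(d) <= math.log2(3)


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=6).filter(sum))
def test_entropy_bounds_hold_for_any_counts(counts):
    labels = tuple(f"e{i}" for i in range(len(counts)))
    d = EventDistribution(labels, tuple(counts))
    h = entropy(d)
    support = sum(c > 0 for c in counts)
    assert -1e-12 <= h <= math.log2(max(support, 1)) + 1e-12


def test_info_amount_is_a_signed_difference():
    assert info_amount(1.0, 0.0) == 1.0
    assert info_amount(0.7, 0.7) == 0.0
    assert info_amount(0.5, 1.0) == -0.5  # surfaced, not clamped
    with pytest.raises(ValueError):
        info_amount(-1.0, 0.0)


def test_information_gained_between_box_experiments():
    # uncertainty of the opaque-box umwelt resolved by perfect discrimination
    h_before = entropy([0.2, 0.3, 0.5])
    h_after = entropy([1.0])
    assert math.isclose(info_amount(h_before, h_after), 1.4854752972273344, abs_tol=1e-12)


# -- discrimination refinement ---------------------------------------------------------


def conditional_entropy(table, own_state, envs, event_fn):
    """H(event | cognition) with conditions = discrimination classes of the
    focal cognizer at own_state, uniform weight per environment state."""
    classes: dict[str, list] = {}
    for e in envs:
        classes.setdefault(table[e], []).append(e)
    m = len(envs)
    h = 0.0
    for members in classes.values():
        events: dict[str, int] = {}
        for e in members:
            ev = event_fn(e)
            events[ev] = events.get(ev, 0) + 1
        h += len(members) / m * entropy(
            EventDistribution(tuple(events), tuple(events.values()))
        )
    return h


def test_refining_discrimination_never_raises_conditional_entropy():
    """Exhaustively over small random worlds: splitting any uncertainty
    class by a table edit cannot increase H(event | cognition)."""
    rng = np.random.default_rng(19)
    for _ in range(25):
        n_env, n_own, n_ev = 4, 4, 3
        envs = [f"e{i}" for i in range(n_env)]
        own_succ = {e: f"s{rng.integers(n_own)}" for e in envs}
        event_of = {e: f"v{rng.integers(n_ev)}" for e in envs}
        h0 = conditional_entropy(own_succ, "s0", envs, event_of.__getitem__)
        used = set(own_succ.values())
        free = [f"s{i}" for i in range(n_own) if f"s{i}" not in used]
        if not free:
            continue
        for e in envs:
            # split e off its class into a fresh successor
            if sum(v == own_succ[e] for v in own_succ.values()) < 2:
                continue
            refined = dict(own_succ, **{e: free[0]})
            h1 = conditional_entropy(refined, "s0", envs, event_of.__getitem__)
            assert h1 <= h0 + 1e-12
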