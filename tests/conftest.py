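import numpy as np
import pytest

from ironnma import NmaConfig, PosteriorSamples, Study, StudyArm, default_registry


@pytest.fixture
def registry():
    return default_registry()


def arm(sid, node, events, total):
    return StudyArm(sid, node, events, total)


def two_arm_study(sid, subgroup, node_t, et, nt, node_c, ec, nc):
    return Study(sid, subgroup, (arm(sid, node_c, ec, nc), arm(sid, node_t, et, nt)))


@pytest.fixture
def samples_factory():
    """Fabricate a PosteriorSamples object from raw basic-parameter draws.

    ``d_full`` is an (N, K) array of draws over all node columns, the
    reference column held at 0.  Used to test ranking/league machinery
    against hand-constructed posteriors.
    """

    def make(d_full, node_labels, reference, direction="bad_outcome"):
        d_full = np.asarray(d_full, float)
        n, k = d_full.shape
        assert k == len(node_labels)
        params = [l for l in node_labels if l != reference]
        cols = [node_labels.index(l) for l in params]
        cfg = NmaConfig(n_chains=1, burn_in=1, kept=n, direction=direction)
        return PosteriorSamples(
            model="consistency",
            param_labels=params,
            node_labels=list(node_labels),
            reference=reference,
            d=d_full[None, :, cols],
            mu=np.zeros((1, n, 1)),
            delta=np.zeros((1, n, 1)),
            tau=np.full((1, n), 0.1),
            subgroup="ckd_g3a5",
            config=cfg,
            flat=None,
        )

    return make
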