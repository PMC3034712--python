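import numpy as np
import pytest

from recallval import PairedSample, VariableMeta


def make_sample(self_report, reference, name="x", kind="quantitative", **kwargs):
    """Small helper: build a PairedSample from two raw vectors."""
    self_report = np.asarray(self_report)
    return PairedSample(
        meta=VariableMeta(name=name, kind=kind, **kwargs),
        ids=np.arange(len(self_report)),
        self_report=self_report,
        reference=np.asarray(reference),
    )


@pytest.fixture
def perfect_sample():
    """Identical self-report and reference values (non-constant)."""
    vals = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.0, 7.7, 8.3])
    return make_sample(vals, vals.copy())


@pytest.fixture
def shifted_sample():
    """Self-report = reference + constant: r = 1 but imperfect agreement."""
    ref = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.0, 7.7, 8.3])
    return make_sample(ref + 2.0, ref)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
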