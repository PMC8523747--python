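import numpy as np
import pandas as pd
import pytest

from clonmeth import synthdata as sd


@pytest.fixture(scope="session")
def small_annotation():
    ann, beds, tss = sd.make_annotation(1200, seed=7)
    return ann, beds, tss


@pytest.fixture(scope="session")
def small_references(small_annotation):
    ann, _, _ = small_annotation
    refs, markers = sd.make_reference_profiles(ann, seed=8)
    return refs, markers


@pytest.fixture(scope="session")
def small_cohort(small_annotation, small_references):
    """70-sample, 1200-probe cohort with planted TET2/DNMT3A effects."""
    ann, _, _ = small_annotation
    refs, _ = small_references
    design = sd.SimDesign(seed=9, n_pairs=30, n_singletons=10, n_probes=1200)
    cohort, truth = sd.simulate_cohort(design, ann, refs)
    return cohort, truth, design


@pytest.fixture(scope="session")
def big_annotation():
    """20k-probe annotation shared by the calibration/recovery experiments."""
    ann, beds, tss = sd.make_annotation(20_000, seed=100)
    refs, markers = sd.make_reference_profiles(ann, seed=101)
    return ann, beds, tss, refs, markers


def random_ewas_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A synthetic EWAS result table with independent signs and P values."""
    p = rng.uniform(size=n)
    est = rng.normal(size=n)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": np.ones(n),
            "stat": est,
            "p": p,
            "direction": np.sign(est).astype(int),
        },
        index=pd.Index([f"cg{i:06d}" for i in range(n)], name="probe"),
    )
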