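import numpy as np
import pandas as pd
import pytest

from fermlink.synthetic import LatentSpec, assemble_dataset
from fermlink.tables import (
    AbundanceTable, FlavourTable, SampleMetadata,
    to_relative, clr_transform, min_max_normalize,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at study-design defaults."""
    return assemble_dataset(LatentSpec(seed=7))


@pytest.fixture(scope="session")
def prepared(default_dataset):
    """Preprocessed blocks for the default dataset."""
    ds = default_dataset
    rel = to_relative(ds.abundance)
    X = clr_transform(ds.abundance).T          # samples x taxa
    fl_norm = min_max_normalize(ds.flavours)
    Y = fl_norm.values.T                       # samples x flavours
    return {"ds": ds, "rel": rel, "X": X, "fl_norm": fl_norm, "Y": Y}


@pytest.fixture(scope="session")
def fitted_model(prepared):
    from fermlink.o2pls import fit_o2pls

    return fit_o2pls(prepared["X"], prepared["Y"], 2, nx=1, ny=1, scale="center")


def small_abundance(counts, taxa=None, kingdoms=None, samples=None):
    counts = np.asarray(counts, dtype=float)
    p, n = counts.shape
    taxa = taxa or [f"t{i}" for i in range(p)]
    kingdoms = kingdoms or ["bacteria"] * p
    samples = samples or [f"s{i}" for i in range(n)]
    return AbundanceTable(
        pd.DataFrame(counts, index=taxa, columns=samples),
        pd.Series(kingdoms, index=taxa),
    )


def small_flavours(values, flavours=None, categories=None, samples=None,
                   subcategories=None):
    values = np.asarray(values, dtype=float)
    q, n = values.shape
    flavours = flavours or [f"f{i}" for i in range(q)]
    categories = categories or ["volatile"] * q
    samples = samples or [f"s{i}" for i in range(n)]
    sub = None
    if subcategories is not None:
        sub = pd.Series(subcategories, index=flavours)
    return FlavourTable(
        pd.DataFrame(values, index=flavours, columns=samples),
        pd.Series(categories, index=flavours),
        sub,
    )


def small_metadata(days, batches=None, samples=None, **extra):
    n = len(days)
    samples = samples or [f"s{i}" for i in range(n)]
    batches = batches or ["b1"] * n
    data = {"day": days, "batch": batches}
    data.update(extra)
    return SampleMetadata(pd.DataFrame(data, index=pd.Index(samples, name="sample_id")))


def principal_angles_deg(A, B):
    Qa, _ = np.linalg.qr(np.asarray(A, dtype=float))
    Qb, _ = np.linalg.qr(np.asarray(B, dtype=float))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s, -1.0, 1.0)))
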