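import numpy as np
import pandas as pd
import pytest

from methmark.datatypes import MethylationMatrix
from methmark.rpmm import BetaMixtureNode, RPMMTree


def make_matrix(beta, detp=None, chrom=None):
    """Build a MethylationMatrix from a raw array with default annotation."""
    beta = np.asarray(beta, dtype=float)
    n, J = beta.shape
    samples = [f"S{i}" for i in range(n)]
    loci = [f"L{j}" for j in range(J)]
    if detp is None:
        detp = np.zeros_like(beta)
    if chrom is None:
        chrom = ["1"] * J
    annot = pd.DataFrame(
        {"gene": [f"G{j}" for j in range(J)], "chromosome": chrom},
        index=pd.Index(loci, name="locus"),
    )
    return MethylationMatrix(
        beta=pd.DataFrame(beta, index=samples, columns=loci),
        detection_p=pd.DataFrame(np.asarray(detp, dtype=float), index=samples, columns=loci),
        annotation=annot,
    )


def make_leaf(a, b, mass, name="leaf"):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return {"a": a, "b": b, "mass": float(mass), "name": name}


def make_tree(leaf_params, n_samples=10):
    """Fabricate an RPMMTree with given leaf beta parameters (for AUC tests)."""
    J = len(leaf_params[0]["a"])
    L = len(leaf_params)
    root = BetaMixtureNode(
        eta=np.full(L, 1.0 / L),
        a=np.stack([lp["a"] for lp in leaf_params]),
        b=np.stack([lp["b"] for lp in leaf_params]),
        resp=np.full((n_samples, L), 1.0 / L),
        loglik=0.0,
        bic=0.0,
        n_effective=float(n_samples),
    )
    post = np.full((n_samples, L), 1.0 / L)
    return RPMMTree(
        root=root,
        leaves=[root],
        leaf_params=leaf_params,
        leaf_posterior=post,
        assignment=post.argmax(axis=1),
        locus_ids=[f"L{j}" for j in range(J)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
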