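import numpy as np
import pandas as pd
import pytest

from dclink.corr import ExpressionPair


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


@pytest.fixture()
def small_pair(rng) -> ExpressionPair:
    """A 12-gene, 8-sample random pair with no planted structure."""
    genes = [f"g{k}" for k in range(12)]
    cx = pd.DataFrame(rng.standard_normal((12, 8)), index=genes,
                      columns=[f"X{k}" for k in range(8)])
    cy = pd.DataFrame(rng.standard_normal((12, 8)), index=genes,
                      columns=[f"Y{k}" for k in range(8)])
    return ExpressionPair(cx, cy)


def _exact_corr_partner(base: np.ndarray, r: float, rng) -> np.ndarray:
    """A vector whose sample Pearson correlation with ``base`` is exactly r."""
    z = rng.standard_normal(base.size)
    bc = base - base.mean()
    zc = z - z.mean()
    zc -= bc * (zc @ bc) / (bc @ bc)  # orthogonalize
    bu = bc / np.linalg.norm(bc)
    zu = zc / np.linalg.norm(zc)
    return r * bu + np.sqrt(1.0 - r**2) * zu


@pytest.fixture()
def reversal_pair(rng) -> tuple[ExpressionPair, list[str]]:
    """Condition Y equals condition X with two gene rows negated.

    Negating a gene's expression vector flips the sign of every one of
    its correlations while leaving all absolute correlations of the
    whole matrix untouched: the canonical correlation-reversal fixture.
    Returns the pair and the flipped gene names.
    """
    n, m = 10, 20
    genes = [f"g{k}" for k in range(n)]
    base = rng.standard_normal(m)
    rows = [base]
    # strongly correlated block (|r| = 0.9 with the base gene)
    for _ in range(4):
        rows.append(_exact_corr_partner(base, 0.9, rng))
    for _ in range(n - 5):
        rows.append(rng.standard_normal(m))
    cx = pd.DataFrame(np.array(rows), index=genes,
                      columns=[f"s{k}" for k in range(m)])
    flipped = ["g1", "g2"]
    cy = cx.copy()
    cy.loc[flipped] = -cy.loc[flipped]
    cy.columns = [f"t{k}" for k in range(m)]
    return ExpressionPair(cx, cy), flipped
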