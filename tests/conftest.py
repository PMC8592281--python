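import numpy as np
import pandas as pd
import pytest

from dietmr.harmonize import InstrumentSet
from dietmr.sumstats import SumStats


def make_sumstats(rows, trait_name="trait", trait_kind="food_item") -> SumStats:
    """Build a SumStats from dict rows (defaults filled for brevity)."""
    full = []
    for r in rows:
        d = {
            "snp_id": r["snp_id"],
            "effect_allele": r.get("effect_allele", "A"),
            "other_allele": r.get("other_allele", "G"),
            "eaf": r.get("eaf", 0.3),
            "beta": r.get("beta", 0.1),
            "se": r.get("se", 0.01),
            "pvalue": r.get("pvalue", 1e-10),
            "n": r.get("n", 10000),
        }
        full.append(d)
    df = pd.DataFrame(full).set_index("snp_id")
    return SumStats(trait_name=trait_name, df=df, trait_kind=trait_kind)


def make_instrument_set(bx, by, sy, sx=None, **kw) -> InstrumentSet:
    bx = np.asarray(bx, float)
    k = len(bx)
    sx = np.zeros(k) + 1e-12 if sx is None else np.asarray(sx, float)
    return InstrumentSet(
        exposure_name=kw.get("exposure_name", "exp"),
        outcome_name=kw.get("outcome_name", "out"),
        snp_ids=kw.get("snp_ids", np.array([f"rs{i}" for i in range(k)], dtype=object)),
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=np.asarray(by, float),
        se_outcome=np.asarray(sy, float),
        pvalue_exposure=kw.get("pvalue_exposure", np.full(k, 1e-10)),
        eaf_exposure=kw.get("eaf_exposure", np.full(k, 0.3)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
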