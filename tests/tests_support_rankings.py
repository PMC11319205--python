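"""Shared helper for building FactorGeneRanking fixtures in tests."""

import numpy as np
import pandas as pd

import fibroniche as fn


def ranking_from_gene_lists(sets: dict, n: int = 50) -> fn.FactorGeneRanking:
    per_factor = {
        f: pd.DataFrame(
            {"weight": np.linspace(1.0, 0.5, len(genes)), "scaled_weight": 1.0},
            index=pd.Index(sorted(genes)),
        )
        for f, genes in sets.items()
    }
    return fn.FactorGeneRanking(per_factor=per_factor, n=n)
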