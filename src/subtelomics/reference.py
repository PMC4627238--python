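"""Published reference values from the CGGA astrocytic-tumour ATRX study.

The bundled table lists, for the 13 chromosome-end genes reported as
concurrently hypermethylated and downregulated in ATRX-low tumours, the
published group means, fold changes and p-values on both platforms.
The count constants summarise the published concurrent-gene tally (18
genes differential on both platforms; 17 hypermethylated, of which 13
downregulated).  These are inputs for worked examples and consistency
checks — everything derived from them (fold changes, quadrant calls,
composition percentages) is recomputed by the package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: published tally of genes differential on both platforms
CONCURRENT_GENES_TOTAL = 18
CONCURRENT_HYPERMETHYLATED = 17
CONCURRENT_HYPOMETHYLATED = 1
HYPERMETHYLATED_DOWNREGULATED = 13

#: published marker stratification parameters (log-scale expression units)
PUBLISHED_CUTOFF = -0.5368
PUBLISHED_AUC = 0.6396


def published_composition() -> dict:
    """Composition percentages recomputed from the published tally."""
    n, n_hyper = CONCURRENT_GENES_TOTAL, CONCURRENT_HYPERMETHYLATED
    return {
        "n_concurrent": n,
        "n_hypermethylated": n_hyper,
        "n_hypomethylated": CONCURRENT_HYPOMETHYLATED,
        "n_hyper_down": HYPERMETHYLATED_DOWNREGULATED,
        "pct_hypermethylated": 100.0 * n_hyper / n,
        "pct_hyper_downregulated": 100.0 * HYPERMETHYLATED_DOWNREGULATED / n_hyper,
    }


def load_integration_reference() -> pd.DataFrame:
    """The published integrative table: 13 hyper_down genes, both platforms."""
    ref = resources.files("subtelomics.data").joinpath("integration_reference.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col="gene")
    return df
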