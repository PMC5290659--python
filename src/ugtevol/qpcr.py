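"""Relative qPCR quantification by the Livak 2^-ddCt method.

Ct values are averaged over technical replicates on the cycle scale,
normalized to a reference gene within each sample (dCt), then to a
calibrator sample (ddCt); fold change = 2^-ddCt, so the calibrator's
fold change is 1 by construction.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["fold_change"]

REQUIRED_COLUMNS = ("gene", "sample", "ct")


def fold_change(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Per (gene, sample) fold change relative to the calibrator sample.

    ``table`` is long-format with columns gene, sample, ct (a replicate
    column is optional; replicates are averaged on the Ct scale first).
    Returns a DataFrame with columns gene, sample, delta_ct, delta_delta_ct,
    fold_change. The reference gene must be measured in every sample and
    every target gene in the calibrator sample.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (table["ct"] <= 0).any() or table["ct"].isna().any():
        raise ValueError("Ct values must be finite and positive")

    mean_ct = table.groupby(["gene", "sample"], sort=False)["ct"].mean()

    ref = mean_ct.xs(reference_gene, level="gene")
    samples = mean_ct.index.get_level_values("sample").unique()
    if not set(samples) <= set(ref.index):
        absent = sorted(set(samples) - set(ref.index))
        raise ValueError(f"reference gene {reference_gene!r} missing in samples {absent}")

    rows = []
    for gene in mean_ct.index.get_level_values("gene").unique():
        if gene == reference_gene:
            continue
        gene_ct = mean_ct.xs(gene, level="gene")
        if calibrator_sample not in gene_ct.index:
            raise ValueError(f"calibrator sample {calibrator_sample!r} missing for {gene!r}")
        dct = gene_ct - ref.loc[gene_ct.index]
        ddct = dct - dct.loc[calibrator_sample]
        for sample in gene_ct.index:
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "delta_ct": dct.loc[sample],
                    "delta_delta_ct": ddct.loc[sample],
                    "fold_change": 2.0 ** (-ddct.loc[sample]),
                }
            )
    return pd.DataFrame(rows)
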