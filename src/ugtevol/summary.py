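"""Distribution summaries over retained Ka/Ks results."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .kaks import KaKsResult

__all__ = ["KsSummary", "ks_summary"]

DEFAULT_BIN_WIDTH = 0.05


@dataclass
class KsSummary:
    """Headline numbers of a Ks / Ka/Ks distribution."""

    n_pairs_retained: int
    mean_ks: float
    mode_ks: float  # midpoint of the highest-count histogram bin
    fraction_ks_lt_1: float
    fraction_ks_lt_0_5: float
    fraction_ratio_lt_1: float
    fraction_ratio_lt_0_6: float
    fraction_ratio_eq_1: float
    fraction_ratio_gt_1: float

    def as_dict(self) -> dict:
        return asdict(self)


def ks_summary(
    results: list[KaKsResult], bin_width: float = DEFAULT_BIN_WIDTH
) -> KsSummary:
    """Summarize retained pairs: Ks histogram mode, threshold fractions.

    The mode is the midpoint of the highest-count histogram bin (bins of
    ``bin_width`` anchored at 0; ties resolved to the lower bin). Ratio
    fractions are over pairs with a defined ratio; Ks fractions over all
    retained pairs.
    """
    retained = [r for r in results if r.filter_status == "retained"]
    if not retained:
        raise ValueError("no retained pairs to summarize")
    ks = np.array([r.Ks for r in retained])
    # half-open bins [i*w, (i+1)*w) anchored at 0; the small tolerance keeps
    # boundary values (0.3 at width 0.05) in their nominal bin despite float
    # division fuzz
    idx = np.floor(ks / bin_width + 1e-9).astype(int)
    counts = np.bincount(idx)
    top = int(np.argmax(counts))  # argmax takes the first (lower) bin on ties
    mode = (top + 0.5) * bin_width

    ratios = np.array([r.ratio for r in retained if r.ratio is not None])
    n_ratio = len(ratios) if len(ratios) else 1
    return KsSummary(
        n_pairs_retained=len(retained),
        mean_ks=float(ks.mean()),
        mode_ks=float(mode),
        fraction_ks_lt_1=float((ks < 1).mean()),
        fraction_ks_lt_0_5=float((ks < 0.5).mean()),
        fraction_ratio_lt_1=float((ratios < 1).sum() / n_ratio),
        fraction_ratio_lt_0_6=float((ratios < 0.6).sum() / n_ratio),
        fraction_ratio_eq_1=float((ratios == 1).sum() / n_ratio),
        fraction_ratio_gt_1=float((ratios > 1).sum() / n_ratio),
    )
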