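"""Gene-set overrepresentation by the one-sided hypergeometric upper tail.

For a gene set of size N, a target list (a GRN) of size T and an observed
overlap k within a universe of U genes, the reported p-value is
P(X ≥ k) for X ~ Hypergeometric(U, N, T), computed in log space so that
extreme tails (down to 1e-230 and beyond) evaluate without underflow.
The report carries the usual columns: genome frequency N/U·100, expected
overlap T·N/U, observed overlap, target frequency k/T·100, and fold
enrichment observed/expected.

The default universe is 33,602 genes — the TAIR10 Arabidopsis gene count,
recovered consistently by inverting the expected-overlap column of the
published enrichment table from at least four independent rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .coexpression import GRN
from .core_io import GeneSet, GeneSetCollection

logger = logging.getLogger("budnet")

__all__ = [
    "DEFAULT_UNIVERSE",
    "EnrichmentConfig",
    "EnrichmentResult",
    "hypergeom_pvalue",
    "enrich_from_counts",
    "hypergeom_enrich",
    "enrichment_report",
    "fold_enrichment",
]

#: TAIR10 Arabidopsis thaliana gene count (reference background)
DEFAULT_UNIVERSE = 33602


@dataclass(frozen=True)
class EnrichmentConfig:
    universe_size: int = DEFAULT_UNIVERSE

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    """One overrepresentation test (one row of the enrichment report)."""

    set_name: str
    N: int                 # gene-set size
    target_size: int       # |GRN|
    n_obs: int             # observed overlap
    universe: int
    pval: float
    log10_pval: float

    @property
    def freq_genome(self) -> float:
        """Gene-set frequency in the genome, ×100."""
        return 100.0 * self.N / self.universe

    @property
    def n_exp(self) -> float:
        """Expected overlap under uniform sampling."""
        return self.target_size * self.N / self.universe

    @property
    def freq_target(self) -> float:
        """Observed frequency in the target list, ×100."""
        return 100.0 * self.n_obs / self.target_size if self.target_size else 0.0

    @property
    def fold(self) -> float:
        return self.n_obs / self.n_exp if self.n_exp > 0 else float("nan")

    def formatted(self) -> dict[str, str]:
        """Report-precision rendering: freqs to 2/1 d.p., NExp to 3 d.p., pval to 2 s.f."""
        return {
            "set_name": self.set_name,
            "N": str(self.N),
            "freq_genome": f"{self.freq_genome:.2f}",
            "n_exp": f"{self.n_exp:.3f}",
            "n_obs": str(self.n_obs),
            "freq_target": f"{self.freq_target:.1f}",
            "pval": f"{self.pval:.1E}",
        }


def hypergeom_pvalue(n_obs: int, set_size: int, target_size: int, universe: int) -> tuple[float, float]:
    """One-sided upper tail P(X ≥ n_obs), with its log10, in log space.

    Returns ``(pval, log10_pval)``; the log10 value remains meaningful even
    when the linear value underflows double precision.
    """
    if n_obs < 0 or n_obs > min(set_size, target_size):
        raise ValueError("n_obs outside [0, min(set_size, target_size)]")
    if max(set_size, target_size) > universe:
        raise ValueError("set larger than universe")
    if n_obs == 0:
        return 1.0, 0.0
    logp = hypergeom.logsf(n_obs - 1, universe, set_size, target_size)
    return float(np.exp(logp)), float(logp / math.log(10.0))


def enrich_from_counts(
    set_name: str,
    set_size: int,
    target_size: int,
    n_obs: int,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> EnrichmentResult:
    """Overrepresentation test from the summary counts alone."""
    pval, log10_pval = hypergeom_pvalue(n_obs, set_size, target_size, config.universe_size)
    return EnrichmentResult(
        set_name=set_name,
        N=set_size,
        target_size=target_size,
        n_obs=n_obs,
        universe=config.universe_size,
        pval=pval,
        log10_pval=log10_pval,
    )


def hypergeom_enrich(
    geneset: GeneSet,
    target: GeneSet,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> EnrichmentResult:
    """Overrepresentation of a gene set within a target gene list."""
    if len(geneset) == 0 or len(target) == 0:
        logger.warning("hypergeom_enrich[%s]: empty input; degenerate result", geneset.name)
        return EnrichmentResult(
            set_name=geneset.name, N=len(geneset), target_size=len(target),
            n_obs=0, universe=config.universe_size, pval=1.0, log10_pval=0.0,
        )
    n_obs = len(geneset.keys & target.keys)
    return enrich_from_counts(geneset.name, len(geneset), len(target), n_obs, config)


def enrichment_report(
    genesets: GeneSetCollection,
    grns: list[GRN],
    config: EnrichmentConfig | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """One overrepresentation row per (gene set, GRN) pair.

    Column conventions follow the published table: genome frequency to
    2 d.p., expected overlap to 3 d.p., target frequency to 1 d.p.,
    p-value to 2 significant figures in scientific notation.  Raw numeric
    columns are included alongside the formatted ones.  ``bh_adjust`` adds
    a Benjamini–Hochberg column across all rows (off by default; the
    published table reports raw p-values).
    """
    if config is None:
        if genesets.universe_size is not None:
            config = EnrichmentConfig(universe_size=genesets.universe_size)
        else:
            config = EnrichmentConfig()
    if len(genesets) == 0 or not grns:
        raise ValueError("enrichment_report needs nonempty gene sets and GRNs")
    rows = []
    for grn in grns:
        for gs in genesets:
            res = hypergeom_enrich(gs, grn.members, config)
            row = {"grn": grn.label, **res.formatted()}
            row.update(
                pval_raw=res.pval, log10_pval=res.log10_pval,
                fold=res.fold, n_exp_raw=res.n_exp,
            )
            rows.append(row)
    frame = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        frame["pval_bh"] = multipletests(frame["pval_raw"], method="fdr_bh")[1]
    return frame


def fold_enrichment(observed: float, expected: float) -> float:
    """Observed/expected ratio (e.g., TF-target counts vs. random lists)."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    return observed / expected
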