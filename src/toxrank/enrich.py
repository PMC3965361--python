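"""Over-representation analysis of per-chemical protein networks.

Each chemical's curated gene network is tested against every category
of a gene-set database with the exact upper-tail hypergeometric test,

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n),

for a draw of n network genes from a universe of N genes containing K
category members, followed by Bonferroni correction.  The tail is
summed in log space: reported categories span p-values below 1e-18,
far beyond naive summation of pmf terms in linear space.

Only over-representation (upper tail) is tested; the databases are
treated as independent Bonferroni families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .records import ChemicalGeneNetwork, EnrichmentResult, GeneSetDatabase

__all__ = [
    "EnrichmentConfig",
    "hypergeom_tail",
    "bonferroni_correct",
    "enrich_network",
    "significance_report",
    "SignificanceReport",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Settings for one enrichment run.

    bonferroni_m
        Family size for the correction; ``"auto"`` uses the number of
        categories tested in the database.
    restrict_to_universe
        When the database declares its universe membership, restrict
        the draw size n to network genes inside the universe (the
        hypergeometric model requires draws from the universe).  When
        no membership list is available, n is the full network size
        against the declared N.
    alpha_report
        Significance level for report labelling (inclusive).
    """

    bonferroni_m: int | str = "auto"
    restrict_to_universe: bool = True
    alpha_report: float = 0.05

    def __post_init__(self) -> None:
        if self.bonferroni_m != "auto" and int(self.bonferroni_m) < 1:
            raise ValueError("bonferroni_m must be >= 1 or 'auto'")


def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Computed as a log-space sum of point masses so that tails below
    1e-300 remain finite and positive.  ``k = 0`` returns exactly 1.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"require 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0  # more category members than the draw or category allows
    log_denom = _log_choose(N, n)
    log_terms = [
        _log_choose(K, i) + _log_choose(N - K, n - i) - log_denom
        for i in range(k, hi + 1)
        if n - i <= N - K  # term is zero when the off-category draw is infeasible
    ]
    if not log_terms:
        return 0.0
    m = max(log_terms)
    total = m + math.log(math.fsum(math.exp(t - m) for t in log_terms))
    # clamp to the smallest positive subnormal: a tail below the float64
    # range is still a positive probability, never zero
    return min(1.0, max(math.exp(total), 5e-324))


def bonferroni_correct(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: min(1, p_raw * m)."""
    if not 0 < p_raw <= 1:
        raise ValueError(f"p_raw must be in (0, 1], got {p_raw}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p_raw * m)


def enrich_network(
    network: ChemicalGeneNetwork,
    db: GeneSetDatabase,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentResult]:
    """Test one chemical's network against every category of one database.

    Results are sorted by corrected p-value ascending, ties by category
    name.  Raises when the draw exceeds the declared universe (a
    mis-declared universe, not a statistical outcome).
    """
    if not network.gene_symbols:
        raise ValueError(f"network for {network.chemical_id} is empty")
    if config.restrict_to_universe and db.universe_genes is not None:
        draw_genes = network.gene_symbols & db.universe_genes
    else:
        draw_genes = network.gene_symbols
    n = len(draw_genes)
    N = db.universe_size
    if n > N:
        raise ValueError(
            f"network {network.chemical_id} ({n} genes) exceeds the declared "
            f"universe of {db.db_name} (N={N})"
        )
    m = len(db.categories) if config.bonferroni_m == "auto" else int(config.bonferroni_m)
    results = []
    for name, members in db.categories.items():
        overlap = draw_genes & members
        p_raw = hypergeom_tail(len(overlap), n, len(members), N)
        results.append(
            EnrichmentResult(
                chemical_id=network.chemical_id,
                db_name=db.db_name,
                category=name,
                overlap_k=len(overlap),
                draw_n=n,
                category_K=len(members),
                universe_N=N,
                p_raw=p_raw,
                p_corrected=bonferroni_correct(p_raw, m),
                overlap_genes=frozenset(overlap),
            )
        )
    results.sort(key=lambda r: (r.p_corrected, r.category))
    return results


@dataclass
class SignificanceReport:
    """Enrichment results partitioned by the reporting convention:
    significant (p_corrected <= alpha, inclusive), not significant
    ("n.s."), and no data ("n.d.": no overlapping genes at all)."""

    significant: list[EnrichmentResult]
    not_significant: list[EnrichmentResult]
    no_data: list[EnrichmentResult]

    def label(self, result: EnrichmentResult) -> str:
        if result in self.no_data:
            return "n.d."
        return "significant" if result in self.significant else "n.s."


def significance_report(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> SignificanceReport:
    significant, ns, nd = [], [], []
    for r in results:
        if r.overlap_k == 0:
            nd.append(r)
        elif r.p_corrected <= alpha:
            significant.append(r)
        else:
            ns.append(r)
    return SignificanceReport(significant=significant, not_significant=ns, no_data=nd)


def write_enrichment_report(
    results: list[EnrichmentResult], path, alpha: float = 0.05
) -> None:
    """TSV report: one row per test with the significance label and the
    overlap genes semicolon-joined."""
    report = significance_report(results, alpha)
    with open(path, "w") as fh:
        fh.write(
            "chemical\tdatabase\tcategory\tk\tn\tK\tN\tp_raw\tp_corrected\t"
            "label\toverlap_genes\n"
        )
        for r in results:
            genes = ";".join(sorted(r.overlap_genes))
            fh.write(
                f"{r.chemical_id}\t{r.db_name}\t{r.category}\t{r.overlap_k}\t"
                f"{r.draw_n}\t{r.category_K}\t{r.universe_N}\t{r.p_raw:.6g}\t"
                f"{r.p_corrected:.6g}\t{report.label(r)}\t{genes}\n"
            )
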