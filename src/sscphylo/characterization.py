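"""Statistical characterization of a single-copy gene set.

Two questions are asked of a shared single-copy set against the genome
background: (i) which flat GO-slim categories are over- or
under-represented (Pearson chi-square on each category's 2x2 table, no
continuity correction, Bonferroni-adjusted within each namespace), and
(ii) whether structural features — exon count, domain count, cDNA
length — differ between the two groups (Welch two-sample, two-tailed
t-test, optionally excluding intronless genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .records import AnnotationRecord, GO_NAMESPACES, ValidationError

__all__ = [
    "EnrichmentResult",
    "StructuralComparison",
    "go_slim_enrichment",
    "structural_comparison",
]

STRUCTURAL_FEATURES = ("exon_count", "domain_count", "cdna_length")


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 chi-square test for one GO-slim category.

    a/b: single-copy genes in / not in the category; c/d: background
    genes in / not in.  ``significant`` means p below the Bonferroni-
    adjusted level alpha/k, k being the number of categories tested in
    the same namespace.
    """

    namespace: str
    category: str
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p: float
    alpha: float
    k: int
    direction: str  # over | under | none

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.k

    @property
    def significant(self) -> bool:
        return self.p < self.adjusted_alpha


@dataclass(frozen=True)
class StructuralComparison:
    feature: str
    mean_focal: float
    mean_background: float
    var_focal: float
    var_background: float
    n_focal: int
    n_background: int
    t: float
    df: float
    p: float
    cutoff: float = 0.01
    exclude_intronless: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.cutoff


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def go_slim_enrichment(
    single_copy_genes: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    background_genes: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every (namespace, category) present in the annotations.

    The focal and background sets must be disjoint ("versus all else").
    A gene lacking annotation for a namespace simply counts in the
    not-in-category cell of every category of that namespace.  Results
    are sorted by namespace then nominal p.
    """
    focal = set(single_copy_genes)
    background = set(background_genes)
    overlap = focal & background
    if overlap:
        raise ValidationError(
            f"focal and background sets overlap: {sorted(overlap)[:5]}"
        )

    categories: dict[str, set[str]] = {ns: set() for ns in GO_NAMESPACES}
    for rec in annotations.values():
        for ns, cats in rec.go_slim.items():
            categories[ns].update(cats)

    def in_category(gene: str, ns: str, cat: str) -> bool:
        rec = annotations.get(gene)
        return rec is not None and cat in rec.go_slim.get(ns, ())

    results: list[EnrichmentResult] = []
    for ns in GO_NAMESPACES:
        cats = sorted(categories[ns])
        k = len(cats)
        for cat in cats:
            a = sum(1 for g in focal if in_category(g, ns, cat))
            b = len(focal) - a
            c = sum(1 for g in background if in_category(g, ns, cat))
            d = len(background) - c
            chi2, p = _chi2_2x2(a, b, c, d)
            pf = a / (a + b) if (a + b) else 0.0
            pb = c / (c + d) if (c + d) else 0.0
            direction = "over" if pf > pb else "under" if pf < pb else "none"
            results.append(
                EnrichmentResult(
                    namespace=ns, category=cat, a=a, b=b, c=c, d=d,
                    chi2=chi2, p=p, alpha=alpha, k=k, direction=direction,
                )
            )
    results.sort(key=lambda r: (GO_NAMESPACES.index(r.namespace), r.p, r.category))
    return results


def structural_comparison(
    single_copy_genes: Iterable[str],
    background_genes: Iterable[str],
    annotations: Mapping[str, AnnotationRecord],
    feature: str,
    exclude_intronless: bool = False,
    cutoff: float = 0.01,
) -> StructuralComparison:
    """Welch two-sample two-tailed t-test on one structural feature.

    ``exclude_intronless`` removes exon_count == 1 genes (candidate
    retrotranspositions) from both groups before testing.  Both groups
    must retain at least two members.
    """
    if feature not in STRUCTURAL_FEATURES:
        raise ValidationError(f"unknown feature {feature!r}")

    def values(genes) -> np.ndarray:
        vals = []
        for g in genes:
            rec = annotations.get(g)
            if rec is None:
                continue
            if exclude_intronless and rec.exon_count == 1:
                continue
            vals.append(getattr(rec, feature))
        return np.asarray(vals, dtype=float)

    x = values(single_copy_genes)
    y = values(background_genes)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"both groups need >= 2 annotated genes after exclusions "
            f"(got {len(x)} and {len(y)})"
        )
    t, p = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0 and vy == 0:
        t, p, df = 0.0, 1.0, float(nx + ny - 2)
    else:
        se2x, se2y = vx / nx, vy / ny
        df = (se2x + se2y) ** 2 / (
            se2x**2 / (nx - 1) + se2y**2 / (ny - 1)
        )
    return StructuralComparison(
        feature=feature,
        mean_focal=float(x.mean()),
        mean_background=float(y.mean()),
        var_focal=float(vx),
        var_background=float(vy),
        n_focal=nx,
        n_background=ny,
        t=float(t),
        df=float(df),
        p=float(p),
        cutoff=cutoff,
        exclude_intronless=exclude_intronless,
    )
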