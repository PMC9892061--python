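import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isodyn.models import Annotation, TranscriptModel
from isodyn.simulate import ScenarioConfig, build_gene_models, simulate_measurements

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_transcript(tid, gene, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(exons),
    )


@pytest.fixture(scope="session")
def toy_reference():
    """Two '+' genes and one '-' gene with known junction structure."""
    return Annotation([
        make_transcript("ref.A1", "geneA", [(100, 200), (300, 400), (500, 600), (700, 800)]),
        make_transcript("ref.A2", "geneA", [(100, 200), (500, 600), (700, 800)]),
        make_transcript("ref.B1", "geneB", [(2000, 2100), (2300, 2400)]),
        make_transcript("ref.C1", "geneC", [(5000, 5400)], strand="-"),
        make_transcript("ref.C2", "geneC", [(4800, 4900), (5000, 5400)], strand="-"),
    ])


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic scenario, generated once for the whole suite."""
    config = ScenarioConfig()
    models = build_gene_models(config, seed=101)
    bundle = simulate_measurements(models, config, seed=102)
    return config, models, bundle


# ---- independent oracles -----------------------------------------------------

def hypergeom_log_pmf(a, row1, row2, col1):
    """log P(table) for the 2x2 table with entries a, row1-a, col1-a, ..."""
    from math import lgamma

    def lc(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    n = row1 + row2
    return lc(row1, a) + lc(row2, col1 - a) - lc(n, col1)


def fisher_oracle(table, rel_tol=1e-7):
    """Two-sided Fisher p by explicit enumeration over all tables with the
    observed margins, summing probabilities <= P(observed)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    logp_obs = hypergeom_log_pmf(a, row1, row2, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = hypergeom_log_pmf(k, row1, row2, col1)
        if lp <= logp_obs + math.log1p(rel_tol):
            total += math.exp(lp)
    return min(total, 1.0)


def binomial_oracle(k1, k2, s1, s2):
    """Tail-doubled two-sided binomial p by direct pmf summation."""
    from math import comb

    n = k1 + k2
    p0 = s1 / (s1 + s2)
    pmf = [comb(n, k) * p0 ** k * (1 - p0) ** (n - k) for k in range(n + 1)]
    lower = sum(pmf[: k1 + 1])
    upper = sum(pmf[k1:])
    return min(1.0, 2.0 * min(lower, upper))


def bh_oracle(pvals):
    """Hand step-up Benjamini-Hochberg."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        adjusted[i] = running
    return adjusted
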