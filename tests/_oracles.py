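"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: enumeration over
genotype tables for the conditional Hardy-Weinberg null, and enumeration
over genotype trios with an exhaustive parental search for the
full-sibship exclusion probability.
"""

import itertools
import math


def enumerate_hwe_tables(allele_counts: dict[int, int]):
    """All genotype tables with the given allele copy counts.

    Returns (table, conditional probability) pairs; probabilities sum to 1.
    """
    alleles = sorted(allele_counts)
    n = sum(allele_counts.values()) // 2
    genos = list(itertools.combinations_with_replacement(alleles, 2))
    tables = []

    def rec(i, remaining, current):
        if i == len(genos):
            if all(v == 0 for v in remaining.values()) and sum(current.values()) == n:
                tables.append({g: c for g, c in current.items() if c > 0})
            return
        a, b = genos[i]
        max_c = min(remaining[a] // (2 if a == b else 1), n - sum(current.values()))
        if a != b:
            max_c = min(max_c, remaining[b])
        for c in range(max_c + 1):
            current[genos[i]] = c
            remaining[a] -= c * (2 if a == b else 1)
            if a != b:
                remaining[b] -= c
            rec(i + 1, remaining, current)
            remaining[a] += c * (2 if a == b else 1)
            if a != b:
                remaining[b] += c
            del current[genos[i]]

    rec(0, dict(allele_counts), {})
    ln_denom = math.lgamma(2 * n + 1)
    out = []
    for t in tables:
        h = sum(c for (a, b), c in t.items() if a != b)
        lp = (math.lgamma(n + 1)
              + sum(math.lgamma(m + 1) for m in allele_counts.values())
              + h * math.log(2) - ln_denom
              - sum(math.lgamma(c + 1) for c in t.values()))
        out.append((t, math.exp(lp)))
    return out


def hwe_exact_p(observed: dict[tuple[int, int], int]) -> float:
    """Exact conditional p: total probability of tables no more probable."""
    counts: dict[int, int] = {}
    for (a, b), c in observed.items():
        counts[a] = counts.get(a, 0) + c
        counts[b] = counts.get(b, 0) + c
    tabs = enumerate_hwe_tables(counts)
    p_obs = next(p for t, p in tabs if t == {g: c for g, c in observed.items() if c > 0})
    return sum(p for _, p in tabs if p <= p_obs + 1e-12)


def homozygote_excess_p(observed: dict[tuple[int, int], int]) -> float:
    """Exact upper-tail probability of >= the observed homozygote count."""
    counts: dict[int, int] = {}
    for (a, b), c in observed.items():
        counts[a] = counts.get(a, 0) + c
        counts[b] = counts.get(b, 0) + c
    hom_obs = sum(c for (a, b), c in observed.items() if a == b)
    tabs = enumerate_hwe_tables(counts)
    return sum(p for t, p in tabs
               if sum(c for (a, b), c in t.items() if a == b) >= hom_obs)


def exclusion_probability_enum(freqs: dict[int, float], group_size: int = 3) -> float:
    """Exact single-locus exclusion probability by full enumeration.

    Parents are searched over every allele of the locus (not only the
    observed ones), keeping this check independent of the implementation's
    observed-allele reduction.
    """
    alleles = sorted(freqs)
    genos = list(itertools.combinations_with_replacement(alleles, 2))

    def gp(g):
        a, b = g
        return freqs[a] * freqs[b] * (2 if a != b else 1)

    def compatible(group):
        for p1 in itertools.combinations_with_replacement(alleles, 2):
            for p2 in itertools.combinations_with_replacement(alleles, 2):
                if all((a in p1 and b in p2) or (b in p1 and a in p2)
                       for a, b in group):
                    return True
        return False

    p_excl = 0.0
    for group in itertools.product(genos, repeat=group_size):
        if not compatible(group):
            p_excl += math.prod(gp(g) for g in group)
    return p_excl
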