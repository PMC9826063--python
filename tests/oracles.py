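"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle recomputes a quantity by the most literal route available —
full per-read CIGAR expansion, exhaustive allele assignment, direct
probability-mass ratios — deliberately sharing no code with the package's
optimized implementations.
"""

from collections import Counter
from scipy.stats import binom

DELETED = "*"


def read_reference_map(read):
    """Expand one read's alignment into {reference position: base or '*'}."""
    out = {}
    ref, q = read.start, 0
    for op, n in read.cigar:
        if op in "M=X":
            for k in range(n):
                out[ref + k] = read.seq[q + k]
            ref += n
            q += n
        elif op == "D":
            for k in range(n):
                out[ref + k] = DELETED
            ref += n
        elif op in "IS":
            q += n
    return out


def pileup_counts(reads, positions):
    """{position: Counter of bases and '*'} by per-read expansion."""
    out = {pos: Counter() for pos in positions}
    for read in reads:
        m = read_reference_map(read)
        for pos in positions:
            if pos in m:
                out[pos][m[pos]] += 1
    return out


def split_counts(reads, dnm):
    """(ref, alt, other) group sizes at the DNM by per-read lookup."""
    ref = alt = other = 0
    for read in reads:
        m = read_reference_map(read)
        b = m.get(dnm.position)
        if b is None:
            continue
        if b == dnm.alt_base:
            alt += 1
        elif b == dnm.ref_base:
            ref += 1
        else:
            other += 1
    return ref, alt, other


def allele_pair_counts(reads, pos1, pos2):
    """Counter over (base at pos1, base at pos2) by per-read double lookup."""
    counts = Counter()
    for read in reads:
        m = read_reference_map(read)
        if pos1 in m and pos2 in m:
            counts[(m[pos1], m[pos2])] += 1
    return counts


def trim_extents(quals, threshold):
    """(left, right) trim lengths by a position-by-position scan."""
    n = len(quals)
    left = 0
    while left < n and quals[left] < threshold:
        left += 1
    right = 0
    while right < n - left and quals[n - 1 - right] < threshold:
        right += 1
    return left, right


def het_posterior(ref_count, alt_count, other_count):
    """Heterozygosity posterior by direct probability-mass ratios.

    Same model as the caller (uniform prior; alt probability eps, 0.5,
    1-eps for hom-ref, het, hom-alt; eps = other fraction / 2, floored at
    1e-3) computed through scipy's binomial pmf instead of log-space sums.
    """
    n = ref_count + alt_count
    if n == 0:
        return 0.0
    depth = n + other_count
    eps = max(other_count / depth / 2.0, 1e-3)
    p = [
        binom.pmf(alt_count, n, eps),
        binom.pmf(alt_count, n, 0.5),
        binom.pmf(alt_count, n, 1.0 - eps),
    ]
    return p[1] / sum(p)


def mendelian_consistent(child_gt, father_gt, mother_gt):
    """True iff some assignment draws one child allele from each parent."""
    a, b = child_gt
    for x, y in ((a, b), (b, a)):
        if x in father_gt and y in mother_gt:
            return True
    return False


def uniquely_attributable(child_gt, father_gt, mother_gt):
    """Exhaustive check that exactly one parental assignment is possible."""
    a, b = child_gt
    if a == b:
        return False
    options = set()
    for x, y in ((a, b), (b, a)):
        if x in father_gt and y in mother_gt:
            options.add((x, y))
    return len(options) == 1
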