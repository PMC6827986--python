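"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written from the defining formulas using raw sums and
explicit loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_from_sums(x, y):
    """Pearson r and two-sided p from raw sums on complete pairs."""
    pairs = [(a, b) for a, b in zip(x, y) if math.isfinite(a) and math.isfinite(b)]
    n = len(pairs)
    sx = sum(a for a, _ in pairs)
    sy = sum(b for _, b in pairs)
    sxx = sum(a * a for a, _ in pairs)
    syy = sum(b * b for _, b in pairs)
    sxy = sum(a * b for a, b in pairs)
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as tdist

    return r, 2 * float(tdist.sf(abs(t), n - 2)), n


def km_table(times, events):
    """Spreadsheet-style product-limit table: list of (t, n_at_risk, d, S)."""
    obs = sorted(zip(times, events))
    event_times = sorted({t for t, e in obs if e})
    s = 1.0
    rows = []
    for ti in event_times:
        n_i = sum(1 for t, _ in obs if t >= ti)
        d_i = sum(1 for t, e in obs if t == ti and e)
        s *= 1 - d_i / n_i
        rows.append((ti, n_i, d_i, s))
    return rows


def logrank_oe(labels, times, events, group1):
    """Manual hypergeometric O/E/V tabulation for the two-group log-rank test."""
    obs = list(zip(labels, times, events))
    O1 = E1 = V = 0.0
    for ti in sorted({t for _, t, e in obs if e}):
        at_risk = [(g, t, e) for g, t, e in obs if t >= ti]
        n = len(at_risk)
        n1 = sum(1 for g, _, _ in at_risk if g == group1)
        d = sum(1 for _, t, e in obs if t == ti and e)
        d1 = sum(1 for g, t, e in obs if t == ti and e and g == group1)
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O1, E1, V


def mh_hazard_ratio(labels, times, events, group1, group2):
    O1, E1, _ = logrank_oe(labels, times, events, group1)
    O2, E2, _ = logrank_oe(labels, times, events, group2)
    return (O1 / E1) / (O2 / E2)


def welch_formulas(a, b):
    """Welch t, Welch-Satterthwaite df and two-sided p from the formulas."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    return t, df, 2 * float(tdist.sf(abs(t), df))


def consensus_bruteforce(records, threshold, min_fraction, min_databases):
    """Exhaustive enumeration of the consensus sieve.

    ``records`` is a list of dicts with keys gene_id, drug_id, class,
    database, r, valid. Returns {(gene, class, direction): selected}.
    """
    genes = sorted({r["gene_id"] for r in records})
    classes = sorted({r["class"] for r in records})
    dbs = sorted({r["database"] for r in records})
    out = {}
    for gene in genes:
        for cls in classes:
            for direction in ("SENSITIVITY", "RESISTANCE"):
                n_pass = 0
                reporting = 0
                for db in dbs:
                    sub = [
                        r
                        for r in records
                        if r["gene_id"] == gene
                        and r["class"] == cls
                        and r["database"] == db
                        and r["valid"]
                    ]
                    if not sub:
                        continue
                    reporting += 1
                    if direction == "SENSITIVITY":
                        hits = sum(1 for r in sub if r["r"] <= -threshold)
                    else:
                        hits = sum(1 for r in sub if r["r"] >= threshold)
                    if hits / len(sub) > min_fraction:
                        n_pass += 1
                if reporting:
                    out[(gene, cls, direction)] = n_pass >= min_databases
    return out


def overlap_bruteforce(sets):
    """Exhaustive set arithmetic over labelled collections."""
    names = sorted(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = len(set(sets[a]) & set(sets[b]))
    all_way = len(set.intersection(*(set(sets[n]) for n in names)))
    ge2 = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ge2 |= set(sets[a]) & set(sets[b])
    return pairwise, all_way, len(ge2)
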