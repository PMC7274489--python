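"""Independent brute-force re-derivations of each descriptor family,
used as oracles against the vectorized encoders."""

import numpy as np

from plantloc.tables import AA_INDEX, STANDARD_AA


def oracle_aac(seq):
    return np.array([seq.count(a) / len(seq) for a in STANDARD_AA])


def oracle_dipep(seq):
    out = np.zeros(400)
    for i in range(len(seq) - 1):
        out[AA_INDEX[seq[i]] * 20 + AA_INDEX[seq[i + 1]]] += 1
    return out / (len(seq) - 1)


def oracle_pseaac(seq, lam, w, table):
    props = table.pseaac_properties
    n = len(seq)
    freqs = oracle_aac(seq)
    thetas = []
    for j in range(1, lam + 1):
        acc = 0.0
        for i in range(n - j):
            a, b = AA_INDEX[seq[i]], AA_INDEX[seq[i + j]]
            corr = 0.0
            for p in range(3):
                corr += (props[p, a] - props[p, b]) ** 2
            acc += corr / 3.0
        thetas.append(acc / (n - j))
    denom = freqs.sum() + w * sum(thetas)
    return np.array(list(freqs / denom) + [w * t / denom for t in thetas])


def oracle_ncc(seq, t):
    return np.concatenate(
        [oracle_aac(seq[:t]), oracle_aac(seq[t : len(seq) - t]), oracle_aac(seq[-t:])]
    )


def oracle_physchem(seq, table):
    out = []
    for _name, members in table.physchem_groups:
        out.append(sum(1 for c in seq if c in members) / len(seq))
    totals = np.zeros(5)
    for c in seq:
        totals += table.atom_counts[AA_INDEX[c]]
    return np.array(out + list(totals / totals.sum()))


def oracle_ctdc(seq, table):
    out = []
    for attr, groups in table.attribute_groups.items():
        for group in groups:
            out.append(sum(1 for c in seq if c in group) / len(seq))
    return np.array(out)


def oracle_ctdt(seq, table):
    out = []
    for attr, groups in table.attribute_groups.items():
        code = {c: k for k, g in enumerate(groups) for c in g}
        coded = [code[c] for c in seq]
        for r, s in ((0, 1), (0, 2), (1, 2)):
            n_pair = sum(
                1
                for i in range(len(seq) - 1)
                if {coded[i], coded[i + 1]} == {r, s}
            )
            out.append(n_pair / (len(seq) - 1))
    return np.array(out)


def oracle_qso(seq, maxlag, w, table):
    D = table.qso_distance
    n = len(seq)
    counts = [seq.count(a) for a in STANDARD_AA]
    taus = []
    for d in range(1, maxlag + 1):
        acc = 0.0
        for i in range(n - d):
            acc += D[AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]] ** 2
        taus.append(acc)
    denom = sum(counts) + w * sum(taus)
    return np.array([c / denom for c in counts] + [w * t / denom for t in taus])


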