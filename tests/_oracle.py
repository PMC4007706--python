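"""Independent brute-force oracles used by the test suites.

The effect oracle rebuilds the full mutant transcript from the genome,
translates it with Biopython, and derives the class from sequence diffs
alone — sharing no code path with the rule-based classifier.
"""

from Bio.Seq import Seq


def transcript_positions(tx):
    ivs = sorted(tx.exons)
    pos = []
    if tx.strand == "+":
        for s, e in ivs:
            pos.extend(range(s, e))
    else:
        for s, e in reversed(ivs):
            pos.extend(range(e - 1, s - 1, -1))
    return pos


def splice_sets(tx, size=2):
    donors, acceptors = set(), set()
    ivs = sorted(tx.exons)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        intron = list(range(e1, s2))
        head, tail = intron[:size], intron[-size:]
        if tx.strand == "+":
            donors.update(head)
            acceptors.update(tail)
        else:
            donors.update(tail)
            acceptors.update(head)
    return donors, acceptors


def classify_oracle(pos0, alt, tx, genome):
    """Class name via full mutant-sequence reconstruction and diffing."""
    donors, acceptors = splice_sets(tx)
    if pos0 in donors:
        return "SPLICE_DONOR"
    if pos0 in acceptors:
        return "SPLICE_ACCEPTOR"
    tpos = transcript_positions(tx)
    raw = "".join(genome.base(tx.contig_id, p) for p in tpos)
    if tx.strand == "-":
        raw = str(Seq(raw).complement())
        alt = str(Seq(alt).complement())
    idx = tpos.index(pos0)
    mut = raw[:idx] + alt + raw[idx + 1 :]

    # UTR boundaries re-derived from the CDS intervals, not the model's
    # own UTR partition
    if tx.strand == "+":
        first_cds_base = sorted(tx.cds_intervals)[0][0]
    else:
        first_cds_base = sorted(tx.cds_intervals)[-1][1] - 1
    u5 = tpos.index(first_cds_base)
    cds_len = sum(e - s for s, e in tx.cds_intervals)

    if idx < u5:
        ref_starts = {i for i in range(u5 - 2) if raw[i : i + 3] == "ATG"}
        mut_starts = {i for i in range(u5 - 2) if mut[i : i + 3] == "ATG"}
        return "START_GAINED" if mut_starts - ref_starts else "UTR_5"
    if idx >= u5 + cds_len:
        return "UTR_3"

    prot_ref = str(Seq(raw[u5 : u5 + cds_len]).translate())
    prot_mut = str(Seq(mut[u5 : u5 + cds_len]).translate())
    ci = (idx - u5) // 3
    if ci == 0 and mut[u5 : u5 + 3] != "ATG":
        return "START_LOST"
    aa_r, aa_m = prot_ref[ci], prot_mut[ci]
    if aa_r == "*" and aa_m == "*":
        return "SYNONYMOUS_STOP"
    if aa_r == "*":
        return "STOP_LOST"
    if aa_m == "*":
        return "STOP_GAINED"
    return "SYNONYMOUS" if prot_ref == prot_mut else "NON_SYNONYMOUS"


def oracle_corpus(result):
    """(pos, ref, alt, transcript) tuples covering every planted site of a
    simulation with every possible alternate base."""
    by_contig = {}
    for g in result.genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    corpus = []
    for site in result.sites:
        for gene in by_contig.get(site.contig_id, ()):
            tx = gene.transcripts[0]
            if tx.contains(site.pos0, 2):
                for alt in "ACGT":
                    if alt != site.ref_allele:
                        corpus.append((site.pos0, site.ref_allele, alt, tx))
    return corpus
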