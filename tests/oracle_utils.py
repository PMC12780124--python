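"""Independent brute-force oracles used by the test suite.

Deliberately naive (position-by-position scans, exhaustive enumeration) and
sharing no code with the implementation they check.
"""

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
        "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
        "D": "H", "H": "D", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def naive_matches(seq: str, motif: str) -> list[int]:
    """Motif start positions by per-position IUPAC comparison (overlaps included)."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(seq[i + k] in IUPAC[motif[k]] for k in range(len(motif))):
            hits.append(i)
    return hits


def naive_cut_sites(seq: str, motif: str, cut_offset: int) -> list[int]:
    """Cut positions from both strands, boundary positions dropped."""
    cuts = {i + cut_offset for i in naive_matches(seq, motif)}
    rc = naive_revcomp(motif)
    if rc != motif:
        cuts.update(i + len(motif) - cut_offset for i in naive_matches(seq, rc))
    cuts.discard(0)
    cuts.discard(len(seq))
    return sorted(cuts)


def all_index_pairs(n: int) -> set[tuple[int, int]]:
    return {(i, j) for i in range(n) for j in range(i + 1, n)}


def random_sequence(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
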