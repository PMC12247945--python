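"""Independent oracles shared by the unit and acceptance tests."""

from itertools import combinations


def sw_oracle(a: str, b: str, matrix, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Exhaustive optimal local alignment score for short sequences.

    Enumerates every order-preserving set of aligned residue pairs between
    the two sequences; unaligned residues between consecutive pairs form
    gap blocks costing ``gap_open + len * gap_extend`` per sequence, and
    residues outside the first/last pair are free (local semantics).  For
    the affine model this enumeration attains the Smith-Waterman optimum,
    by a route entirely independent of dynamic programming.

    Returns the best positive score, or ``None`` when no alignment scores
    above zero.
    """
    la, lb = len(a), len(b)
    S = [[float(matrix[x, y]) for y in b] for x in a]
    best = 0.0
    for k in range(1, min(la, lb) + 1):
        for qi in combinations(range(la), k):
            for ti in combinations(range(lb), k):
                sc = 0.0
                for t in range(k):
                    sc += S[qi[t]][ti[t]]
                    if t:
                        gq = qi[t] - qi[t - 1] - 1
                        gt = ti[t] - ti[t - 1] - 1
                        if gq:
                            sc -= gap_open + gq * gap_extend
                        if gt:
                            sc -= gap_open + gt * gap_extend
                if sc > best:
                    best = sc
    return best if best > 0 else None


def resolvable_losses(clade, k: int = 3) -> set:
    """Planted losses whose syntenic neighborhood is intact, from truth.

    A loss is resolvable when, on each side, at least one of the ``k``
    nearest reference genes is present and intact in the target species,
    and the innermost such anchors land on one target contig (no assembly
    breakpoint between them).  A side with no reference genes at all (the
    focal gene sits at the reference contig edge) is instead covered by
    the contig boundary, which requires two intact anchors on the other
    side (to orient the block) on a single contig.
    """
    genes = clade.gene_ids
    idx = {g: i for i, g in enumerate(genes)}
    out = set()
    for (g, sp), st in clade.truth.status.items():
        if st != "lost":
            continue
        i = idx[g]
        up = [genes[j] for j in range(i - 1, max(-1, i - 1 - k), -1)]
        down = [genes[j] for j in range(i + 1, min(len(genes), i + 1 + k))]
        sides = []
        ok = True
        for cand in (up, down):
            present = [
                a for a in cand if clade.truth.status[(a, sp)] == "present_intact"
            ]
            if cand and not present:
                ok = False
            sides.append((cand, present))
        if not ok:
            continue
        (cu, pu), (cd, pd_) = sides
        ctg_u = [clade.truth.coordinates[(a, sp)][0] for a in pu]
        ctg_d = [clade.truth.coordinates[(a, sp)][0] for a in pd_]
        if pu and pd_:
            if ctg_u[0] == ctg_d[0]:
                out.add((g, sp))
        elif not cu:
            if len(pd_) >= 2 and ctg_d[0] == ctg_d[1]:
                out.add((g, sp))
        elif not cd:
            if len(pu) >= 2 and ctg_u[0] == ctg_u[1]:
                out.add((g, sp))
    return out
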