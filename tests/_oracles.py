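"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with naive loops and plain data structures,
deliberately avoiding the package's own coordinate/track machinery, so a
bug in the implementation cannot hide in a shared code path.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STARTS = {"ATG", "CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT"}
OFFSETS = {**{n: 12 for n in range(26, 31)}, **{n: 13 for n in range(31, 34)}, 34: 14}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class RawModel:
    """Plain transcript description: exon walk done longhand."""

    def __init__(self, gene, tid, chrom, strand, exons, cds_start, cds_end):
        self.gene, self.tid, self.chrom, self.strand = gene, tid, chrom, strand
        self.exons, self.cds_start, self.cds_end = exons, cds_start, cds_end
        walk = []
        for s, e in sorted(exons):
            walk.extend(range(s, e))
        if strand == "-":
            walk = walk[::-1]
        self.walk = walk  # genomic position per transcript coordinate
        self.pos2t = {g: t for t, g in enumerate(walk)}
        first_cds_g = cds_start if strand == "+" else cds_end - 1
        last_cds_g = cds_end - 1 if strand == "+" else cds_start
        self.cds_start_tx = self.pos2t[first_cds_g]
        self.cds_end_tx = self.pos2t[last_cds_g] + 1

    def seq(self, genome):
        bases = [genome[self.chrom][g] for g in self.walk]
        if self.strand == "-":
            bases = [COMPLEMENT[b] for b in bases]
        return "".join(bases)


def raw_models(models):
    """Convert package TranscriptModel objects into RawModel descriptions."""
    return [
        RawModel(m.gene_id, m.transcript_id, m.chrom, m.strand, m.exons,
                 m.cds_start, m.cds_end)
        for m in models
    ]


def oracle_psite(five_prime: int, strand: str, length: int) -> int | None:
    if length not in OFFSETS:
        return None
    off = OFFSETS[length]
    return five_prime + off if strand == "+" else five_prime - off


def oracle_track(reads) -> dict:
    """Recount P-sites over a read list with plain loops."""
    counts: dict[tuple[str, str], dict[int, int]] = {}
    rejected = 0
    for r in reads:
        p = oracle_psite(r.five_prime, r.strand, r.length)
        if p is None:
            rejected += 1
            continue
        d = counts.setdefault((r.chrom, r.strand), {})
        d[p] = d.get(p, 0) + 1
    return counts, rejected


def _codon(genome, chrom, strand, c, model: RawModel | None):
    if model is not None and c in model.pos2t:
        t = model.pos2t[c]
        s = model.seq(genome)
        if t + 3 <= len(s):
            return s[t:t + 3]
    seq = genome[chrom]
    if strand == "+":
        if 0 <= c and c + 3 <= len(seq):
            return seq[c:c + 3]
        return None
    if c - 2 >= 0 and c + 1 <= len(seq):
        return rc(seq[c - 2:c + 1])
    return None


def oracle_call_tis(genome, models, ltm, chx, thresholds):
    """Literal position-by-position TIS calling.

    *ltm*/*chx* are {(chrom, strand): {pos: count}}; *models* RawModel list.
    *thresholds* is the package TISThresholds (plain attribute access only).
    Returns a set of comparable tuples.
    """
    by_loc = {}
    for m in models:
        by_loc.setdefault((m.chrom, m.strand), []).append(m)
    for v in by_loc.values():
        v.sort(key=lambda m: m.tid)

    def models_at(chrom, strand, pos):
        return [m for m in by_loc.get((chrom, strand), []) if pos in m.pos2t]

    def n_total(track, m: RawModel):
        d = track.get((m.chrom, m.strand), {})
        return sum(d.get(g, 0) for g in m.walk)

    def r_of(x, n):
        return (x / n) * 10.0 if n > 0 else 0.0

    # ---- peak finding -----------------------------------------------------
    cands = {}
    for (chrom, strand), counts in ltm.items():
        for p, cp in counts.items():
            if cp <= 0:
                continue
            if max(counts.get(q, 0) for q in range(p - 3, p + 4)) > cp:
                continue
            hits = models_at(chrom, strand, p)
            model = hits[0] if hits else None
            opts = []
            for delta in (0, -1, 1):
                c = p - delta if strand == "+" else p + delta
                codon = _codon(genome, chrom, strand, c, model)
                if codon in STARTS:
                    five = c if strand == "+" else -c
                    opts.append((abs(delta), 0 if codon == "ATG" else 1, five, c, codon))
            if not opts:
                continue
            opts.sort()
            _, _, _, anchor, codon = opts[0]
            key = (chrom, strand, anchor)
            if key not in cands or cp > cands[key][0]:
                cands[key] = (cp, anchor, codon)

    # ---- equal-window competition -----------------------------------------
    surviving = {}
    for (chrom, strand), _ in list(ltm.items()):
        group = sorted(
            [(k, v) for k, v in cands.items() if k[0] == chrom and k[1] == strand],
            key=lambda kv: kv[0][2],
        )
        alive = [True] * len(group)
        for i in range(len(group)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(group)):
                if not alive[j]:
                    continue
                (ka, va), (kb, vb) = group[i], group[j]
                if kb[2] - ka[2] > 3:
                    break
                # decide loser
                if va[0] != vb[0]:
                    loser = i if va[0] < vb[0] else j
                else:
                    a_atg, b_atg = va[2] == "ATG", vb[2] == "ATG"
                    if a_atg != b_atg:
                        loser = j if a_atg else i
                    elif strand == "+":
                        loser = j if va[1] < vb[1] else i
                    else:
                        loser = j if va[1] > vb[1] else i
                alive[loser] = False
        for ok, (k, v) in zip(alive, group):
            if ok:
                surviving[k] = v

    # ---- scoring & thresholds ---------------------------------------------
    called = {}
    for (chrom, strand, anchor), (cp, _, codon) in surviving.items():
        contexts = models_at(chrom, strand, anchor)
        recs = []
        for m in contexts:
            t = m.pos2t[anchor]
            cs, ce = m.cds_start_tx, m.cds_end_tx
            if t == cs:
                cat = "dbTIS"
            elif t < cs:
                cat = "leader5"
            elif t >= ce:
                cat = "leader3"
            elif (t - cs) % 3 == 0:
                cat = "cds_dTIS_inframe"
            else:
                cat = "cds_other_frame"
            win = [m.walk[u] for u in (t - 1, t, t + 1) if 0 <= u < len(m.walk)]
            x_l = sum(ltm.get((chrom, strand), {}).get(g, 0) for g in win)
            x_c = sum(chx.get((chrom, strand), {}).get(g, 0) for g in win)
            r_l, r_c = r_of(x_l, n_total(ltm, m)), r_of(x_c, n_total(chx, m))
            recs.append((m.gene, m.tid, cat, x_l, r_l, r_c, r_l - r_c))
        if not recs:
            flank = thresholds.intergenic_flank
            win = [anchor - 1, anchor, anchor + 1]
            x_l = sum(ltm.get((chrom, strand), {}).get(g, 0) for g in win)
            x_c = sum(chx.get((chrom, strand), {}).get(g, 0) for g in win)
            pseudo = range(anchor - flank, anchor + flank + 1)
            nl = sum(ltm.get((chrom, strand), {}).get(g, 0) for g in pseudo)
            nc = sum(chx.get((chrom, strand), {}).get(g, 0) for g in pseudo)
            r_l, r_c = r_of(x_l, nl), r_of(x_c, nc)
            recs.append(
                (f"intergenic:{chrom}:{anchor}", "-", "intergenic", x_l, r_l, r_c, r_l - r_c)
            )
        db = [r for r in recs if r[2] == "dbTIS"]
        pool = db if db else recs
        best = max(pool, key=lambda r: (r[6], r[1]))
        gene, tid, cat, x_l, r_l, r_c, rdiff = best
        if x_l >= thresholds.min_count[cat] and rdiff >= thresholds.min_rdiff[cat]:
            key = (chrom, anchor, strand)
            if key not in called or rdiff > called[key][6]:
                called[key] = (gene, tid, cat, x_l, r_l, r_c, rdiff, codon, "called")

    # ---- dbTIS rescue -----------------------------------------------------
    rescued = {}
    for m in models:
        anchor = m.walk[m.cds_start_tx]
        key = (m.chrom, anchor, m.strand)
        if key in called and called[key][2] == "dbTIS":
            continue
        chx_d = chx.get((m.chrom, m.strand), {})
        chx_cds = sum(
            chx_d.get(m.walk[t], 0) for t in range(m.cds_start_tx, m.cds_end_tx)
        )
        if chx_cds < thresholds.rescue_min_chx:
            continue
        t = m.cds_start_tx
        win = [m.walk[u] for u in (t - 1, t, t + 1) if 0 <= u < len(m.walk)]
        x_l = sum(ltm.get((m.chrom, m.strand), {}).get(g, 0) for g in win)
        x_c = sum(chx_d.get(g, 0) for g in win)
        r_l, r_c = r_of(x_l, n_total(ltm, m)), r_of(x_c, n_total(chx, m))
        codon = _codon(genome, m.chrom, m.strand, anchor, m) or "NNN"
        rec = (m.gene, m.tid, "dbTIS", x_l, r_l, r_c, r_l - r_c, codon, "rescued_dbTIS")
        if key not in rescued or rec[6] > rescued[key][6]:
            rescued[key] = rec
    for key, rec in rescued.items():
        if key not in called:
            called[key] = rec

    # ---- per-gene dedup ---------------------------------------------------
    best_by_gene = {}
    for (chrom, anchor, strand), rec in called.items():
        key = (rec[0], anchor)
        if key not in best_by_gene or rec[6] > best_by_gene[key][1][6]:
            best_by_gene[key] = ((chrom, anchor, strand), rec)
    out = set()
    for (gene, anchor), ((chrom, a, strand), rec) in best_by_gene.items():
        out.add(
            (gene, rec[1], chrom, strand, anchor, rec[7], rec[2], rec[3],
             round(rec[4], 9), round(rec[5], 9), round(rec[6], 9), rec[8])
        )
    return out


def called_tis_tuples(called):
    """Comparable tuples from package CalledTIS records."""
    return {
        (r.gene, r.transcript, r.chrom, r.strand, r.position, r.codon, r.category,
         r.ltm_count, round(r.r_ltm, 9), round(r.r_chx, 9), round(r.rdiff, 9),
         r.status)
        for r in called
    }


def oracle_translate(nt: str) -> str:
    """Codon-table walk using an independently keyed table."""
    table = {}
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    for i, aa in enumerate(aas):
        table[bases[i // 16] + bases[i // 4 % 4] + bases[i % 4]] = aa
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa = table[nt[i:i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)
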