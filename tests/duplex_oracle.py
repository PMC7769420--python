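"""Independent brute-force enumerator of accepted sRNA/target alignments.

Used as the correctness oracle for the package's binding-site scanner.  It
re-implements the complementarity rules from scratch (its own base-pair
classification and penalty bookkeeping) and explores every alignment shape
— every anchor, up to two bulge runs of any affordable length on either
strand — by depth-first recursion.  The only pruning is on conditions that
can never be undone by extending an alignment (penalty already above the
cap, too many seed mismatches, a mismatch at a forbidden position on the
current path), so the search remains exhaustive.

``enumerate_accepted`` returns the scanner's observable contract: the set of
(target_start, penalty, n_bulges, n_mismatches) after per-start
deduplication with the same tie-break rule the scanner documents.
"""

from srnadig.duplex import ScoringConfig

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _classify(srna_base: str, target_base: str) -> str:
    if _COMP.get(srna_base) == target_base:
        return "WC"
    if (srna_base, target_base) in (("G", "T"), ("T", "G")):
        return "GU"
    return "MM"


def enumerate_accepted(
    srna: str, target: str, cfg: ScoringConfig = ScoringConfig()
) -> set[tuple[int, float, int, int]]:
    L = len(srna)
    T = len(target)
    max_len = 1
    while cfg.bulge_cost(max_len + 1) <= cfg.max_score:
        max_len += 1
    raw: list[tuple[int, int, float, tuple, int]] = []

    def walk(i, t, pen, seed_mm, shape, nmm, e):
        if t < 1 or t > T:
            return
        tb = target[t - 1]
        if tb == "N":
            return
        state = _classify(srna[i - 1], tb)
        if state == "MM":
            if i in cfg.forbidden_mm_positions:
                return
            nmm += 1
            if cfg.seed_start <= i <= cfg.seed_end:
                seed_mm += 1
                if seed_mm > cfg.max_seed_mismatches:
                    return
                pen += cfg.mm_penalty_seed
            else:
                pen += cfg.mm_penalty_nonseed
        elif state == "GU":
            pen += cfg.gu_penalty
        if pen > cfg.max_score:
            return
        if i == L:
            if "N" not in target[t - 1:e]:  # whole window must be N-free
                raw.append((t, e, pen, shape, nmm))
            return
        walk(i + 1, t - 1, pen, seed_mm, shape, nmm, e)
        if len(shape) < cfg.max_bulges:
            for b in range(1, max_len + 1):
                bpen = pen + cfg.bulge_cost(b)
                if bpen > cfg.max_score:
                    break
                if i + b <= L - 1:
                    walk(i + b + 1, t - 1, bpen, seed_mm,
                         shape + ((i, "srna", b),), nmm, e)
                walk(i + 1, t - 1 - b, bpen, seed_mm,
                     shape + ((i, "target", b),), nmm, e)

    for e in range(1, T + 1):
        walk(1, e, 0.0, 0, (), 0, e)

    # per-start dedup: min penalty, then fewer bulges, fewer mismatches,
    # leftmost (smallest target end)
    best: dict[int, tuple] = {}
    for start, e, pen, shape, nmm in raw:
        key = (pen, len(shape), nmm, e, shape)
        if start not in best or key < best[start]:
            best[start] = key
    return {(s, k[0], k[1], k[2]) for s, k in best.items()}


def enumerate_accepted_noprune(
    srna: str, target: str, cfg: ScoringConfig = ScoringConfig()
) -> set[tuple[int, float, int, int]]:
    """Dead-simple full enumeration over explicit shape tuples, no recursion
    and no pruning beyond structural bounds.  Only usable on tiny targets;
    validates the recursive oracle itself."""
    L = len(srna)
    T = len(target)
    max_len = 1
    while cfg.bulge_cost(max_len + 1) <= cfg.max_score:
        max_len += 1

    def shapes():
        yield ()
        for side in ("srna", "target"):
            for b in range(1, max_len + 1):
                hi = L - 1 - b if side == "srna" else L - 1
                for p in range(1, hi + 1):
                    yield ((p, side, b),)
        sides = ("srna", "target")
        for s1 in sides:
            for b1 in range(1, max_len + 1):
                for s2 in sides:
                    for b2 in range(1, max_len + 1):
                        if cfg.bulge_cost(b1) + cfg.bulge_cost(b2) > cfg.max_score:
                            continue
                        h1 = L - 1 - b1 if s1 == "srna" else L - 1
                        h2 = L - 1 - b2 if s2 == "srna" else L - 1
                        gap = b1 if s1 == "srna" else 0
                        for p1 in range(1, h1 + 1):
                            for p2 in range(p1 + gap + 1, h2 + 1):
                                yield ((p1, s1, b1), (p2, s2, b2))

    def score(e, shape):
        bulge_after = {p: (side, b) for p, side, b in shape}
        pen = sum(cfg.bulge_cost(b) for _, _, b in shape)
        seed_mm = nmm = 0
        i, t = 1, e
        while i <= L:
            if not (1 <= t <= T) or target[t - 1] == "N":
                return None
            state = _classify(srna[i - 1], target[t - 1])
            if state == "GU":
                pen += cfg.gu_penalty
            elif state == "MM":
                if i in cfg.forbidden_mm_positions:
                    return None
                nmm += 1
                if cfg.seed_start <= i <= cfg.seed_end:
                    seed_mm += 1
                    pen += cfg.mm_penalty_seed
                else:
                    pen += cfg.mm_penalty_nonseed
            t -= 1
            if i in bulge_after:
                side, b = bulge_after[i]
                if side == "srna":
                    i += b
                else:
                    t -= b
            i += 1
        if seed_mm > cfg.max_seed_mismatches or pen > cfg.max_score:
            return None
        if "N" in target[t:e]:
            return None
        return t + 1, pen, len(shape), nmm

    best: dict[int, tuple] = {}
    for e in range(1, T + 1):
        for shape in shapes():
            res = score(e, shape)
            if res is None:
                continue
            start, pen, nb, nmm = res
            key = (pen, nb, nmm, e, shape)
            if start not in best or key < best[start]:
                best[start] = key
    return {(s, k[0], k[1], k[2]) for s, k in best.items()}
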