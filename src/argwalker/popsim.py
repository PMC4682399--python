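"""Forward-time two-allele hotspot simulator with true-ARG extraction.

Generates the study's synthetic inputs: phased haplotypes of diploid
individuals over a ~100-SNP, 200 kb window containing one recombination
hotspot whose per-meiosis crossover probability is controlled by a biallelic
causal SNP (allele 1 = "hot", allele 0 = "cold").  A Wright–Fisher
population evolves forward in time; each meiosis may cross over at the
hotspot midpoint — with probability multiplied by ``hot_cold_ratio`` when
the transmitting haplotype carries the hot allele — and at a uniformly
placed background position elsewhere.  Biased gene conversion (BGC) is
modelled at the causal site only: when a hotspot crossover happens in a
causal-site heterozygote, the transmitted causal allele is the cold
(hotspot-disrupting) allele with probability ``0.5 + bgc_rate``.

Because the whole pedigree of gametes is recorded, the *true* ancestral
recombination graph of the sampled haplotypes can be extracted by tracing
ancestral genomic segments backwards; the walker can therefore be tested
without any external ARG reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .arg_graph import ArgGraph, ArgValidationError, load_arg, read_edge_list, read_leaf_labels, write_edge_list, write_leaf_labels

__all__ = [
    "Scenario",
    "HaplotypeSample",
    "simulate_sample",
    "make_scenario_grid",
    "write_sample",
    "read_sample",
    "read_hapmap_phased",
]

_MODES = ("two-allele", "all-hot", "all-cold")


@dataclass(frozen=True)
class Scenario:
    """Configuration of one simulated hotspot scenario.

    Defaults are the "Normal" condition: 90 diploid individuals, about 100
    SNPs over 200 kb, a centred causal SNP at MAF 0.5, hot/cold crossover
    ratio 10, no BGC.
    """

    n_individuals: int = 90
    n_snps: int | None = None  # None: jittered uniformly in [90, 110]
    span_bp: int = 200_000
    hot_cold_ratio: float = 10.0
    causal_index: int | None = None  # None: centre SNP
    causal_maf: float = 0.5
    bgc_rate: float = 0.0
    base_crossover: float = 0.02  # cold-allele hotspot crossover prob per meiosis
    pop_size: int = 500  # breeding diploids
    generations: int = 200
    background_rate: float = 0.002  # non-hotspot crossover prob per meiosis
    hotspot_snp_width: int = 1  # inter-SNP boundaries spanned by the hotspot
    n_founders: int = 40  # founder haplotypes seeding the population
    seed: int = 0
    mode: str = "two-allele"
    tag: str = ""

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n_snps is not None and self.n_snps < 3:
            raise ValueError("n_snps must be >= 3")
        if not 0.0 <= self.bgc_rate <= 0.5:
            raise ValueError("bgc_rate must be in [0, 0.5]")
        if self.hot_cold_ratio < 1.0:
            raise ValueError("hot_cold_ratio must be >= 1")
        if not 0.0 < self.causal_maf <= 0.5:
            raise ValueError("causal_maf must be in (0, 0.5]")
        for name in ("base_crossover", "background_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.base_crossover * self.hot_cold_ratio > 1.0:
            raise ValueError("base_crossover * hot_cold_ratio exceeds 1")
        if self.n_individuals < 2 or self.pop_size < 2 or self.generations < 1:
            raise ValueError("n_individuals, pop_size, generations must be >= 2, 2, 1")
        if self.n_individuals > self.pop_size:
            raise ValueError("cannot sample more individuals than the population holds")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.hotspot_snp_width < 1:
            raise ValueError("hotspot_snp_width must be >= 1")


@dataclass(frozen=True)
class HaplotypeSample:
    """Phased haplotypes with truth labels and the sample's true ARG."""

    matrix: np.ndarray  # (n_hap, n_snp) uint8 in {0,1}, segregating sites only
    positions: np.ndarray  # bp coordinates, strictly increasing
    hap_ids: tuple[str, ...]
    truth: dict[str, str]  # hap_id -> "hot" | "cold"
    true_arg: ArgGraph
    causal_snp_index: int | None  # column of the causal SNP, None if fixed
    scenario: Scenario
    stats: dict = field(default_factory=dict)  # realized meiosis/crossover counts

    @property
    def n_hap(self) -> int:
        return self.matrix.shape[0]


# ------------------------------------------------------------- simulation


def simulate_sample(s: Scenario, *, max_retries: int = 50) -> HaplotypeSample:
    """Run the forward Wright–Fisher simulation described in the module docs.

    Deterministic given ``s.seed``.  If the causal allele is lost to drift
    (or the sampled haplotypes are monomorphic at the causal site) in
    two-allele mode, the simulation is retried with a derived seed up to
    ``max_retries`` times before raising.
    """
    s.validate()
    for attempt in range(max_retries):
        sample = _simulate_once(s, attempt)
        if sample is not None:
            return sample
    raise RuntimeError(
        f"causal allele lost to drift in {max_retries} attempts (seed {s.seed}); "
        "consider a higher causal_maf or shorter history"
    )


def _simulate_once(s: Scenario, attempt: int) -> HaplotypeSample | None:
    rng = np.random.default_rng([attempt, s.seed & 0x7FFFFFFF])
    n_snps = int(s.n_snps) if s.n_snps is not None else int(rng.integers(90, 111))
    causal = int(s.causal_index) if s.causal_index is not None else n_snps // 2
    if not 0 <= causal < n_snps:
        raise ValueError(f"causal_index {causal} outside SNP span")
    positions = np.sort(rng.choice(s.span_bp, size=n_snps, replace=False)) + 1
    # The hotspot is a short interval adjacent to the causal SNP: crossovers
    # fall on one of `hotspot_snp_width` inter-SNP boundaries starting just
    # right of the causal site, so the rate-determining causal allele always
    # travels with the transmitted gamete (transmission distortion is
    # modelled separately, via bgc_rate).
    lo = min(causal + 1, n_snps - 1)
    hi = min(causal + s.hotspot_snp_width, n_snps - 1)
    hot_bounds = np.arange(lo, hi + 1)

    # Founder-structured initialization: a biallelic variant at intermediate
    # frequency is an old polymorphism, so its carriers form deep allelic
    # clades with distinct haplotype backgrounds.  The population is seeded
    # from a limited pool of founder haplotypes, a fraction causal_maf of
    # which carry the hot allele; forward recombination then mixes flanking
    # material across the clades.
    n_pop_hap = 2 * s.pop_size
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    founders = (rng.random((s.n_founders, n_snps)) < freqs).astype(np.uint8)
    if s.mode == "two-allele":
        n_hot = min(max(int(round(s.n_founders * s.causal_maf)), 1), s.n_founders - 1)
        founders[:, causal] = 0
        founders[rng.permutation(s.n_founders)[:n_hot], causal] = 1
    else:
        founders[:, causal] = 1 if s.mode == "all-hot" else 0
    founder_assign = rng.integers(0, s.n_founders, size=n_pop_hap)
    pop = founders[founder_assign]

    cols = np.arange(n_snps)
    pedigree = []  # per generation: (template_idx, other_idx, hot_cross, b_hot, bg_cross, b_bg)
    stats = {"hot_meioses": 0, "cold_meioses": 0,
             "hot_crossovers": 0, "cold_crossovers": 0}
    for _ in range(s.generations):
        # each diploid offspring k receives gamete 2k from one parent and
        # gamete 2k+1 from an independently drawn parent
        parent = rng.integers(0, s.pop_size, size=n_pop_hap)
        which = rng.integers(0, 2, size=n_pop_hap)
        template_idx = 2 * parent + which
        other_idx = 2 * parent + (1 - which)

        hot = pop[template_idx, causal] == 1
        p_cross = s.base_crossover * np.where(hot, s.hot_cold_ratio, 1.0)
        hot_cross = rng.random(n_pop_hap) < p_cross
        b_hot = rng.choice(hot_bounds, size=n_pop_hap)
        bg_cross = rng.random(n_pop_hap) < s.background_rate
        b_bg = rng.integers(1, n_snps, size=n_pop_hap)

        toggle = (hot_cross[:, None] & (cols >= b_hot[:, None])) ^ (
            bg_cross[:, None] & (cols >= b_bg[:, None])
        )
        gametes = np.where(toggle, pop[other_idx], pop[template_idx])

        if s.bgc_rate > 0 and s.mode == "two-allele":
            het = pop[template_idx, causal] != pop[other_idx, causal]
            conv = hot_cross & het
            if conv.any():
                to_cold = rng.random(int(conv.sum())) < 0.5 + s.bgc_rate
                gametes[np.flatnonzero(conv), causal] = np.where(to_cold, 0, 1)

        stats["hot_meioses"] += int(hot.sum())
        stats["cold_meioses"] += int((~hot).sum())
        stats["hot_crossovers"] += int((hot_cross & hot).sum())
        stats["cold_crossovers"] += int((hot_cross & ~hot).sum())
        pedigree.append((template_idx, other_idx, hot_cross, b_hot, bg_cross, b_bg))
        pop = gametes

    sampled = np.sort(rng.choice(s.pop_size, size=s.n_individuals, replace=False))
    hap_rows = np.concatenate([2 * sampled, 2 * sampled + 1])
    hap_rows.sort()
    matrix = pop[hap_rows].copy()
    causal_alleles = matrix[:, causal]
    if s.mode == "two-allele":
        # the causal MAF is a property of the analysed sample: reject
        # realizations that drifted away from the target (or lost the allele)
        maf = min(causal_alleles.mean(), 1 - causal_alleles.mean())
        if abs(maf - s.causal_maf) > 0.1 or causal_alleles.min() == causal_alleles.max():
            return None

    hap_ids = tuple(f"h{i:03d}" for i in range(len(hap_rows)))
    truth = {
        hid: ("hot" if a == 1 else "cold") for hid, a in zip(hap_ids, causal_alleles)
    }
    true_arg = _extract_true_arg(pedigree, hap_rows, hap_ids, n_snps, founder_assign)

    # fixed sites are not SNPs: drop monomorphic columns from the output
    seg = matrix.min(axis=0) != matrix.max(axis=0)
    causal_out = int(seg[:causal].sum()) if seg[causal] else None
    return HaplotypeSample(
        matrix=matrix[:, seg],
        positions=positions[seg],
        hap_ids=hap_ids,
        truth=truth,
        true_arg=true_arg,
        causal_snp_index=causal_out,
        scenario=s,
        stats=dict(stats, attempt=attempt),
    )


# ------------------------------------------------- true-ARG extraction


def _pieces(hot_cross: bool, bg_cross: bool, b_hot: int, b_bg: int, n: int):
    """Split [0, n) into (template-piece, other-piece) interval lists."""
    pts = sorted(p for p, on in ((b_hot, hot_cross), (b_bg, bg_cross)) if on)
    if len(pts) == 2 and pts[0] == pts[1]:
        pts = []  # coincident crossovers cancel
    bounds = [0] + pts + [n]
    tmpl, oth = [], []
    for k in range(len(bounds) - 1):
        seg = (bounds[k], bounds[k + 1])
        if seg[0] < seg[1]:
            (tmpl if k % 2 == 0 else oth).append(seg)
    return tmpl, oth


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo < hi:
                out.append((lo, hi))
    return out


def _union(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    ivs = sorted(a + b)
    out: list[tuple[int, int]] = []
    for s1, e1 in ivs:
        if out and s1 <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e1))
        else:
            out.append((s1, e1))
    return out


def _extract_true_arg(
    pedigree, hap_rows, hap_ids, n_snps, founder_assign
) -> ArgGraph:
    """Trace ancestral segments of the sample back through the pedigree.

    A gamete is kept as a graph node only while it carries window material
    ancestral to the sample; a crossover gamete whose ancestral material all
    lies on one side of its breakpoints keeps a single parent, so retained
    nodes with two parents are exactly the sampled-lineage breakpoints
    inside the window.  Lineages reaching generation 0 coalesce at their
    founder haplotype (copies of one founder share unmodelled pre-epoch
    ancestry).  Non-branching chains are contracted afterwards.
    """
    n_gen = len(pedigree)
    full = [(0, n_snps)]
    active: dict[int, list] = {int(h): list(full) for h in hap_rows}
    node_of = {(n_gen, int(h)): i for i, h in enumerate(hap_rows)}
    edges: set[tuple[int, int]] = set()
    next_id = len(hap_rows)

    for g in range(n_gen - 1, -1, -1):
        template_idx, other_idx, hot_cross, b_hot, bg_cross, b_bg = pedigree[g]
        nxt: dict[int, list] = {}
        for hap, ivs in active.items():
            tmpl_piece, oth_piece = _pieces(
                bool(hot_cross[hap]),
                bool(bg_cross[hap]),
                int(b_hot[hap]),
                int(b_bg[hap]),
                n_snps,
            )
            child = node_of[(g + 1, hap)]
            for parent_hap, piece in (
                (int(template_idx[hap]), tmpl_piece),
                (int(other_idx[hap]), oth_piece),
            ):
                inherit = _intersect(ivs, piece)
                if not inherit:
                    continue
                key = (
                    ("f", int(founder_assign[parent_hap]))
                    if g == 0
                    else (g, parent_hap)
                )
                if key not in node_of:
                    node_of[key] = next_id
                    next_id += 1
                if node_of[key] != child:
                    edges.add((node_of[key], child))
                nxt[parent_hap] = _union(nxt.get(parent_hap, []), inherit)
        active = nxt

    labels = {i: hap_ids[i] for i in range(len(hap_rows))}
    edges = _contract_pure_subtrees(edges, labels)
    edges, labels = _contract_chains(edges, labels)
    return load_arg(sorted(edges), labels)


def _contract_pure_subtrees(edges: set[tuple[int, int]], labels: dict[int, str]):
    """Flatten recombination-free subtrees to stars around their roots.

    The emitted graph resolves ancestry at the granularity of recombination
    events, as sequence-based reconstructions do: the internal coalescent
    structure of a clade that contains no recombination node is not
    resolvable from haplotype data, so its leaves are attached directly to
    the clade root.  Mass then splits evenly inside such clades and profile
    variation is driven by recombination structure.
    """
    pred: dict[int, set] = {}
    succ: dict[int, set] = {}
    nodes = set()
    for u, v in edges:
        succ.setdefault(u, set()).add(v)
        pred.setdefault(v, set()).add(u)
        nodes.update((u, v))
    recomb = {v for v in nodes if len(pred.get(v, ())) >= 2 and succ.get(v)}

    # nodes from which a recombination node is reachable downward
    reaches: dict[int, bool] = {}

    def reaches_recomb(v, _stack=None):
        if v in reaches:
            return reaches[v]
        todo, seen, found = [v], set(), False
        while todo:
            x = todo.pop()
            if x in seen:
                continue
            seen.add(x)
            if x in recomb and x != v:
                found = True
                break
            if x in reaches:
                if reaches[x]:
                    found = True
                    break
                continue
            todo.extend(succ.get(x, ()))
        reaches[v] = found
        return found

    pure = {
        v
        for v in nodes
        if v not in labels and v not in recomb and succ.get(v) and not reaches_recomb(v)
    }
    # maximal pure nodes: pure with no pure parent (pure nodes have <= 1 parent)
    out = set()
    star_leaves: dict[int, set] = {}
    for u, v in edges:
        if u in pure and (not pred.get(u) or next(iter(pred[u])) not in pure):
            # u is a maximal pure node: collect every leaf below it
            if u not in star_leaves:
                todo, seen, lv = [u], set(), set()
                while todo:
                    x = todo.pop()
                    if x in seen:
                        continue
                    seen.add(x)
                    if x in labels:
                        lv.add(x)
                    todo.extend(succ.get(x, ()))
                star_leaves[u] = lv
    drop = set()
    for m, lv in star_leaves.items():
        for x in lv:
            out.add((m, x))
    for m in star_leaves:  # everything strictly below m is pure or leaf: drop it
        todo = list(succ.get(m, ()))
        while todo:
            x = todo.pop()
            if x in labels or x in drop:
                continue
            drop.add(x)
            todo.extend(succ.get(x, ()))
    for u, v in edges:
        if u in star_leaves and v in drop:
            continue
        if u in drop:
            continue
        if v in drop:
            continue
        out.add((u, v))
    return out


def _contract_chains(edges: set[tuple[int, int]], labels: dict[int, str]):
    """Remove in-degree-1/out-degree-1 nodes, fusing their edges.

    Contraction is skipped when it would create a parallel edge (the ARG
    data model forbids duplicate edges).
    """
    pred: dict[int, set] = {}
    succ: dict[int, set] = {}
    nodes = set()
    for u, v in edges:
        succ.setdefault(u, set()).add(v)
        pred.setdefault(v, set()).add(u)
        nodes.update((u, v))
    changed = True
    while changed:
        changed = False
        for node in list(nodes):
            if node in labels:
                continue
            ps = pred.get(node, set())
            cs = succ.get(node, set())
            if len(ps) == 1 and len(cs) == 1:
                (p,), (c,) = ps, cs
                if c in succ.get(p, set()):
                    continue  # would duplicate edge p->c
                succ[p].discard(node)
                succ[p].add(c)
                pred[c].discard(node)
                pred[c].add(p)
                nodes.discard(node)
                succ.pop(node, None)
                pred.pop(node, None)
                changed = True
    # dense, deterministic renumbering: leaves keep their ids (0..n_leaf-1)
    remaining = sorted(nodes)
    mapping = {old: new for new, old in enumerate(remaining)}
    out_edges = {(mapping[u], mapping[v]) for u, vs in succ.items() for v in vs}
    out_labels = {mapping[k]: v for k, v in labels.items() if k in mapping}
    return out_edges, out_labels


# ------------------------------------------------------------- scenarios


def make_scenario_grid(reps: int = 50, base_seed: int = 20150) -> list[Scenario]:
    """The four simulation sweeps plus the all-hot/all-cold controls.

    Sweeps (each with ``reps`` replicate seeds, defaults elsewhere):
    hot/cold ratio in {1, 5, 10, 15, 20}; causal-SNP position at five even
    offsets from the window centre to its edge; causal MAF in
    {0.1, ..., 0.5}; BGC rate in {0, 0.1, ..., 0.5}.  Stable ordering and
    derived seeds make the grid deterministic.
    """
    scenarios: list[Scenario] = []
    counter = 0

    def emit(**kw):
        nonlocal counter
        for rep in range(reps):
            scenarios.append(
                Scenario(seed=base_seed + 7919 * counter + rep, **kw)
            )
        counter += 1

    for ratio in (1, 5, 10, 15, 20):
        emit(hot_cold_ratio=float(ratio), tag=f"ratio={ratio}")
    # position sweep uses a fixed SNP count so offsets are well defined
    n_snps = 100
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        idx = int(round(n_snps // 2 + frac * (n_snps - 2 - n_snps // 2)))
        emit(n_snps=n_snps, causal_index=idx, tag=f"position={frac:.2f}")
    for maf in (0.1, 0.2, 0.3, 0.4, 0.5):
        emit(causal_maf=maf, tag=f"maf={maf:.1f}")
    for bgc in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        emit(bgc_rate=bgc, tag=f"bgc={bgc:.1f}")
    emit(mode="all-hot", tag="all-hot")
    emit(mode="all-cold", tag="all-cold")
    for sc in scenarios:
        sc.validate()
    return scenarios


# ------------------------------------------------------------- file I/O


def write_sample(sample: HaplotypeSample, out_dir) -> None:
    """Write a sample as plain-text TSV/JSON files (lossless round trip)."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "haplotypes.tsv", "w") as fh:
        fh.write("hap_id\t" + "\t".join(str(p) for p in sample.positions) + "\n")
        for i, hid in enumerate(sample.hap_ids):
            fh.write(hid + "\t" + "\t".join(str(a) for a in sample.matrix[i]) + "\n")
    with open(d / "truth.tsv", "w") as fh:
        fh.write("hap_id\tlabel\n")
        for hid in sample.hap_ids:
            fh.write(f"{hid}\t{sample.truth[hid]}\n")
    write_edge_list(sample.true_arg, d / "arg_edges.tsv")
    write_leaf_labels(sample.true_arg, d / "arg_labels.tsv")
    meta = asdict(sample.scenario)
    meta["causal_snp_index"] = sample.causal_snp_index
    with open(d / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_sample(in_dir) -> HaplotypeSample:
    d = Path(in_dir)
    with open(d / "haplotypes.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "hap_id":
            raise ArgValidationError(f"{d}/haplotypes.tsv:1: bad header")
        positions = np.asarray([int(p) for p in header[1:]])
        hap_ids, rows = [], []
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != positions.size + 1:
                raise ArgValidationError(
                    f"{d}/haplotypes.tsv:{lineno}: expected {positions.size} alleles, "
                    f"got {len(parts) - 1}"
                )
            hap_ids.append(parts[0])
            rows.append([int(a) for a in parts[1:]])
    truth = {}
    with open(d / "truth.tsv") as fh:
        fh.readline()
        for line in fh:
            hid, label = line.rstrip("\n").split("\t")
            truth[hid] = label
    arg = load_arg(read_edge_list(d / "arg_edges.tsv"), read_leaf_labels(d / "arg_labels.tsv"))
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    causal_out = meta.pop("causal_snp_index", None)
    scenario = Scenario(**meta)
    return HaplotypeSample(
        matrix=np.asarray(rows, dtype=np.uint8),
        positions=positions,
        hap_ids=tuple(hap_ids),
        truth=truth,
        true_arg=arg,
        causal_snp_index=causal_out,
        scenario=scenario,
    )


def read_hapmap_phased(path):
    """Read a HapMap-Phase-3-style phased file (rsID rows, haplotype columns).

    Expected layout: a header line ``rsID position <hap col> <hap col> ...``
    followed by one row per SNP with base letters per haplotype.  At each
    SNP the alphabetically smaller base is coded 0.  Returns
    ``(matrix, positions, hap_ids, snp_ids)`` with haplotypes as rows.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3:
            raise ArgValidationError(f"{path}:1: expected rsID, position, haplotypes")
        hap_ids = header[2:]
        snp_ids, positions, columns = [], [], []
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(hap_ids) + 2:
                raise ArgValidationError(
                    f"{path}:{lineno}: expected {len(hap_ids)} alleles"
                )
            snp_ids.append(parts[0])
            positions.append(int(parts[1]))
            bases = parts[2:]
            uniq = sorted(set(bases))
            if len(uniq) > 2:
                raise ArgValidationError(f"{path}:{lineno}: more than two alleles")
            columns.append([0 if b == uniq[0] else 1 for b in bases])
    matrix = np.asarray(columns, dtype=np.uint8).T
    return matrix, np.asarray(positions), tuple(hap_ids), tuple(snp_ids)
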