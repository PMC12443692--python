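"""I/O, synthetic fixtures, verification batteries, and scaling studies.

Everything here is deterministic for fixed arguments and seeds; operation
counts (not wall-clock) are the performance signal throughout.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .base_paths import bp_algorithm4, bp_linear, bp_oracle
from .base_suffixes import (
    bs_algorithm1,
    bs_algorithm2,
    bs_linear,
    bs_oracle,
    find_reference_annotation,
)
from .errors import TextFormatError
from .instrument import OpCounter
from .oshr import build_oshr, oshr_classify
from .suffix_core import DEFAULT_SENTINEL, SuffixTree, Text, build_suffix_tree

__all__ = [
    "OpCounter",
    "ScalingReport",
    "EquivalenceReport",
    "read_and_preprocess_fasta",
    "preprocess_string",
    "generate_synthetic",
    "run_equivalence_suite",
    "run_scaling_study",
    "BS_ALGORITHMS",
    "BP_ALGORITHMS",
    "diff_bs_tables",
    "diff_bp_tables",
]

DNA = ("A", "C", "G", "T")


def preprocess_string(raw: str, sentinel: str = DEFAULT_SENTINEL) -> Text:
    """Strip whitespace/newlines, uppercase, append the sentinel."""
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise TextFormatError("empty sequence after preprocessing")
    if sentinel in cleaned:
        raise TextFormatError("sequence contains the sentinel character %r" % sentinel)
    return Text.from_raw(cleaned, sentinel)


def read_and_preprocess_fasta(
    path, multi: str = "concat", sentinel: str = DEFAULT_SENTINEL
) -> Text:
    """Load FASTA or raw text into a single preprocessed :class:`Text`.

    Header lines and newlines are removed and nucleotides uppercased.
    Multi-record FASTA files are concatenated in file order unless
    ``multi="reject"``.
    """
    if multi not in ("concat", "reject"):
        raise ValueError("multi must be 'concat' or 'reject'")
    raw = Path(path).read_text()
    if raw.lstrip().startswith(">"):
        from Bio import SeqIO
        from io import StringIO

        records = list(SeqIO.parse(StringIO(raw), "fasta"))
        if not records:
            raise TextFormatError("no FASTA records in %s" % path)
        if multi == "reject" and len(records) > 1:
            raise TextFormatError("multi-record FASTA rejected (%d records)" % len(records))
        seq = "".join(str(r.seq) for r in records)
    else:
        seq = raw
    return preprocess_string(seq, sentinel)


def generate_synthetic(
    model: str,
    length: int,
    alphabet: Sequence[str] = DNA,
    seed: int = 0,
    sentinel: str = DEFAULT_SENTINEL,
) -> Text:
    """Deterministic synthetic texts (sentinel appended).

    Models: ``uniform`` i.i.d. characters; ``markov`` a seeded first-order
    chain; ``repeat_heavy`` tandem-duplicated slices of a short random core
    (stresses SLS fan-in); ``run`` a single repeated character, which
    maximizes the tree height.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    alphabet = tuple(sorted(set(alphabet)))
    if sentinel in alphabet:
        raise TextFormatError("alphabet must not contain the sentinel")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    rng = random.Random((model, length, alphabet, seed, sentinel).__repr__())
    if model == "uniform":
        seq = "".join(rng.choice(alphabet) for _ in range(length))
    elif model == "markov":
        k = len(alphabet)
        trans = {c: rng.choices(alphabet, weights=[rng.random() + 0.05 for _ in range(k)], k=length) for c in alphabet}
        out = [rng.choice(alphabet)]
        ptr = {c: 0 for c in alphabet}
        for _ in range(length - 1):
            c = out[-1]
            out.append(trans[c][ptr[c]])
            ptr[c] += 1
        seq = "".join(out)
    elif model == "repeat_heavy":
        core_len = max(1, length // 8)
        core = [rng.choice(alphabet) for _ in range(core_len)]
        out = list(core)
        while len(out) < length:
            lo = rng.randrange(core_len)
            hi = min(core_len, lo + 1 + rng.randrange(core_len))
            piece = core[lo:hi]
            if piece and rng.random() < 0.3:  # occasional point mutation
                piece = list(piece)
                piece[rng.randrange(len(piece))] = rng.choice(alphabet)
            out.extend(piece)
        seq = "".join(out[:length])
    elif model == "run":
        seq = alphabet[0] * length
    else:
        raise ValueError("unknown model %r" % model)
    return Text.from_raw(seq, sentinel)


BS_ALGORITHMS = {
    "oracle": lambda tree, view, ann, counter=None: bs_oracle(tree, view, counter),
    "a1": lambda tree, view, ann, counter=None: bs_algorithm1(tree, view, counter),
    "a2": lambda tree, view, ann, counter=None: bs_algorithm2(tree, view, counter),
    "a3": lambda tree, view, ann, counter=None: bs_linear(tree, view, ann, counter),
}

BP_ALGORITHMS = {
    "oracle": lambda tree, view, ann, counter=None: bp_oracle(tree, view, counter),
    "a4": lambda tree, view, ann, counter=None: bp_algorithm4(tree, view, counter),
    "a5": lambda tree, view, ann, counter=None: bp_linear(tree, view, ann, counter),
}


def diff_bs_tables(t1, t2) -> list:
    """Node-level differences between two base-suffix tables."""
    out = []
    for nid in sorted(set(t1.by_node) | set(t2.by_node)):
        a = t1.by_node.get(nid)
        b = t2.by_node.get(nid)
        if a != b:
            out.append((nid, a, b))
    return out


def diff_bp_tables(t1, t2) -> list:
    return diff_bs_tables(t1, t2)


@dataclass
class EquivalenceRow:
    label: str
    seed: Optional[int]
    n: int
    sigma: int
    internal: int
    total_bs: int
    total_bp: int
    ok: bool


@dataclass
class EquivalenceReport:
    seed: int
    rows: list = field(default_factory=list)
    failures: list = field(default_factory=list)  # (label, seed, kind, node diffs)

    @property
    def ok(self) -> bool:
        return not self.failures

    def summary(self) -> str:
        lines = ["label\tn\tsigma\tinternal\ttotal_bs\ttotal_bp\tok"]
        for r in self.rows:
            lines.append(
                "%s\t%d\t%d\t%d\t%d\t%d\t%s" % (r.label, r.n, r.sigma, r.internal, r.total_bs, r.total_bp, r.ok)
            )
        return "\n".join(lines)


def _fibonacci_string(min_len: int) -> str:
    a, b = "A", "AB"
    while len(b) < min_len:
        a, b = b, b + a
    return b


def default_battery(seed: int = 0, n_random: int = 200) -> list:
    """(label, Text) fixtures: seeded random strings plus adversarial shapes."""
    rng = random.Random(seed)
    fixtures = []
    n_uniform = (n_random * 3) // 5
    for i in range(n_uniform):
        length = rng.randint(2, 300)
        fixtures.append(
            ("uniform-%d" % i, generate_synthetic("uniform", length, DNA, seed=seed * 10007 + i))
        )
    for i in range(n_random - n_uniform):
        length = rng.randint(2, 300)
        # skewed two-letter alphabet via a biased markov chain
        fixtures.append(
            ("twoletter-%d" % i, generate_synthetic("markov", length, ("A", "B"), seed=seed * 20011 + i))
        )
    for i in range(6):
        length = rng.randint(10, 200)
        fixtures.append(
            ("repeat-%d" % i, generate_synthetic("repeat_heavy", length, DNA, seed=seed * 31 + i))
        )
    for k in (1, 2, 3, 5, 20, 100):
        fixtures.append(("run-A^%d" % k, generate_synthetic("run", k, ("A",), seed=0)))
    for k in (1, 3, 10, 50):
        fixtures.append(("ab-(AB)^%d" % k, Text.from_raw("AB" * k)))
    fixtures.append(("fibonacci", Text.from_raw(_fibonacci_string(233))))
    fixtures.append(("worked-example", Text.from_raw("AGCATAATTTAACTAAG")))
    return fixtures


def run_equivalence_suite(
    sizes: Optional[Sequence[int]] = None,
    reps: int = 200,
    seed: int = 0,
    fixtures: Optional[list] = None,
) -> EquivalenceReport:
    """Assert pairwise agreement of all BS and BP algorithms on a battery.

    Also checks the conservation law (total base suffixes == n, union ==
    {0..n-1}) and the sigma*n bound on the number of base paths.  ``sizes``
    optionally replaces the default random length range with fixed lengths.
    """
    report = EquivalenceReport(seed=seed)
    if fixtures is None:
        if sizes:
            fixtures = []
            for i, ln in enumerate(sizes):
                for r in range(max(1, reps // len(sizes))):
                    fixtures.append(
                        ("uniform-n%d-r%d" % (ln, r), generate_synthetic("uniform", ln, DNA, seed=seed + 97 * i + r))
                    )
        else:
            fixtures = default_battery(seed=seed, n_random=reps)
    for label, text in fixtures:
        tree = build_suffix_tree(text)
        view = build_oshr(tree)
        ann = find_reference_annotation(tree, view)
        bs_tables = {name: fn(tree, view, ann) for name, fn in BS_ALGORITHMS.items()}
        bp_tables = {name: fn(tree, view, ann) for name, fn in BP_ALGORITHMS.items()}
        ok = True
        ref_bs = bs_tables["oracle"]
        for name, table in bs_tables.items():
            diffs = diff_bs_tables(ref_bs, table)
            if diffs:
                ok = False
                report.failures.append((label, seed, "bs:" + name, diffs[:5]))
        ref_bp = bp_tables["oracle"]
        for name, table in bp_tables.items():
            diffs = diff_bp_tables(ref_bp, table)
            if diffs:
                ok = False
                report.failures.append((label, seed, "bp:" + name, diffs[:5]))
        n = tree.n
        if ref_bs.total != n or ref_bs.global_union() != set(range(n)):
            ok = False
            report.failures.append((label, seed, "bs:conservation", []))
        if ref_bp.total > tree.sigma * n:
            ok = False
            report.failures.append((label, seed, "bp:bound", []))
        report.rows.append(
            EquivalenceRow(label, seed, n, tree.sigma, tree.num_internal, ref_bs.total, ref_bp.total, ok)
        )
    return report


@dataclass
class ScalingFit:
    slope: float
    r2: float


@dataclass
class ScalingReport:
    model: str
    seed: int
    entries: dict = field(default_factory=dict)  # algo -> [(n, op_count)]
    fits: dict = field(default_factory=dict)  # algo -> ScalingFit
    flagged: list = field(default_factory=list)  # linear algos whose slope exceeds 1.15

    def summary(self) -> str:
        lines = ["algo\tn\top_count"]
        for algo, pairs in self.entries.items():
            for n, ops in pairs:
                lines.append("%s\t%d\t%d" % (algo, n, ops))
        lines.append("algo\tslope\tR2")
        for algo, fit in self.fits.items():
            lines.append("%s\t%.4f\t%.5f" % (algo, fit.slope, fit.r2))
        return "\n".join(lines)


_LINEAR_ALGOS = {"bs_a3", "bp_a5"}

_ALGO_TABLE = {
    "bs_oracle": ("bs", "oracle"),
    "bs_a1": ("bs", "a1"),
    "bs_a2": ("bs", "a2"),
    "bs_a3": ("bs", "a3"),
    "bp_oracle": ("bp", "oracle"),
    "bp_a4": ("bp", "a4"),
    "bp_a5": ("bp", "a5"),
}


def run_scaling_study(
    algorithms: Sequence[str],
    sizes: Sequence[int],
    model: str = "uniform",
    seed: int = 0,
    alphabet: Sequence[str] = DNA,
) -> ScalingReport:
    """Fit log(op_count) against log(n) per algorithm.

    Requires >= 4 sizes spanning roughly 1.5 orders of magnitude (the guard
    accepts 1.4 so that the canonical 30x series 1e4..3e5 qualifies).
    Linear algorithms whose fitted slope exceeds 1.15 are flagged.
    """
    from scipy import stats

    sizes = sorted(sizes)
    if len(sizes) < 4:
        raise ValueError("scaling study needs at least 4 sizes")
    if math.log10(sizes[-1] / sizes[0]) < 1.4 - 1e-9:
        raise ValueError("sizes must span at least ~1.5 orders of magnitude")
    for name in algorithms:
        if name not in _ALGO_TABLE:
            raise ValueError("unknown algorithm %r" % name)
    report = ScalingReport(model=model, seed=seed, entries={a: [] for a in algorithms})
    for ln in sizes:
        if model == "run":
            text = generate_synthetic("run", ln, (alphabet[0],), seed=seed)
        else:
            text = generate_synthetic(model, ln, alphabet, seed=seed)
        tree = build_suffix_tree(text)
        view = build_oshr(tree)
        needs_ann = any(_ALGO_TABLE[a][1] == "a3" for a in algorithms)
        ann = find_reference_annotation(tree, view) if needs_ann else None
        for name in algorithms:
            kind, key = _ALGO_TABLE[name]
            fn = BS_ALGORITHMS[key] if kind == "bs" else BP_ALGORITHMS[key]
            counter = OpCounter(n=tree.n, sigma=tree.sigma)
            fn(tree, view, ann, counter)
            report.entries[name].append((tree.n, counter.total()))
    for name, pairs in report.entries.items():
        xs = [math.log10(n) for n, _ in pairs]
        ys = [math.log10(max(1, ops)) for _, ops in pairs]
        fit = stats.linregress(xs, ys)
        report.fits[name] = ScalingFit(slope=float(fit.slope), r2=float(fit.rvalue) ** 2)
        if name in _LINEAR_ALGOS and report.fits[name].slope > 1.15:
            report.flagged.append(name)
    return report
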