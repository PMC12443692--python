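# otidx

Linear indexing of the strings under every internal node of a suffix tree.

Given a sentinel-terminated text, `otidx` builds an annotated suffix tree
(Ukkonen construction, suffix links, DFS intervals), inverts the suffix
links into the **OSHR tree** over the internal nodes, and enumerates

* **base suffixes** — for each internal node `x`, the suffix positions in
  `SU(x)` that appear under no OSHR child of `x`.  Globally the base
  suffixes are exactly `{0..n-1}`, one per text position.
* **base paths** — top/bottom internal-node pairs whose suffix-link
  preimage pair does not exist in ancestor/descendant relation; at most
  `sigma * n` of them exist.

Appending each node's base suffixes during an OSHR post-order yields the
**OT index**: one global list of length `n` plus per-node inclusive offset
pairs whose slice reconstructs `SU(x)` without descending the tree.  The
index answers exact pattern-matching queries directly.

Each enumeration has multiple interchangeable routes — a defining set-
difference oracle, intermediate `O(n h)`-style algorithms, and a linear
route (reference-node machinery for base suffixes, a memoized covered-depth
sweep for base paths) — that are cross-checked for equality on every input.

## Layout

| module | contents |
| --- | --- |
| `otidx.suffix_core` | `Text`, `STNode`, `SuffixTree`, construction, label lookup, `su_set`/`s_set`/`pu_set`, descendant tests |
| `otidx.oshr` | `OSHRView`, classification, post-order, suffix-link ancestor chains |
| `otidx.base_suffixes` | `bs_oracle`, `bs_algorithm1`, `bs_algorithm2`, reference annotation, `bs_linear` |
| `otidx.base_paths` | `bp_oracle`, `bp_algorithm4`, `bp_linear` |
| `otidx.ot_index` | OT index construction, suffix-set and pattern queries, invariant verifier |
| `otidx.workbench` | FASTA/raw preprocessing, synthetic generators, equivalence battery, op-count scaling studies |
| `otidx.cli` | the `otidx` command |

## CLI

```sh
# structural counts (leaves, internal nodes, OSHR partition, height)
otidx build --text AGCATAATTTAACTAAG

# base suffixes / base paths with a chosen algorithm (oracle|a1|a2|a3, oracle|a4|a5)
otidx base-suffixes --text AGCATAATTTAACTAAG --algo a3 --out bs.tsv
otidx base-paths    --fasta genome.fa --algo a5 --out bp.tsv

# OT index (optionally restricted to an OSHR subtree), pattern queries
otidx ot    --text AGCATAATTTAACTAAG --subtree T --json idx.json
otidx query --text AGCATAATTTAACTAAG --pattern TAA   # -> 4 9 13

# cross-check all algorithms + OT invariants; exit 1 on any disagreement
otidx verify --text AGCATAATTTAACTAAG --quick
otidx verify --battery --reps 100 --seed 0

# synthetic fixtures and op-count scaling studies
otidx synth --model run --length 4 --alphabet A     # -> AAAA$
otidx scale --algos bs_a3,bp_a5 --sizes 10000,30000,100000,300000 --seed 1
```

Exit codes: 0 success, 1 verification failure, 2 usage error.

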