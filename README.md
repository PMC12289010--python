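# fragtiler

Decompose error-prone long sequencing reads into an ordered, non-overlapping
tiling of short known DNA fragments.

## The problem

Synthetic combinatorial DNA libraries are built by randomly ligating short
constituent fragments (here 10–20 nt) into longer products, which are then
sequenced — typically on Oxford Nanopore instruments, whose reads are long
and cheap but noisy, with an especially error-dense region at the read
start. Standard read mappers rely on exact k-mer anchors and cannot locate
fragments this short under that error load. `fragtiler` answers the
question those experiments pose: *given the pool of known fragments, which
fragments — in which order — make up each read?*

## The algorithm

For a read `r` and each fragment `f` in the pool, the fragment is aligned
semi-globally (infix mode: the whole fragment must align, unaligned read
flanks are free) and scored by its **alignment identity**

```
I(f, r) = (|A| − E(f, r)) / |A|
```

where `E(f, r)` is the edit distance of the infix alignment and `|A|` its
number of columns (free flanks excluded). The covering is built greedily
and recursively:

1. align every fragment to the uncovered segment; take the placement with
   the highest identity (ties: first fragment in library order);
2. if that identity is below the threshold `T` (default 0.75) the segment
   stays uncovered; otherwise fix the placement at `r[i, j)` and recurse on
   `r[0, i)` and `r[j, |r|)`;
3. stop on segments of ≤ 5 bp.

Alignment uses edlib capped at `k = ⌈|f|·(1/T − 1)⌉` edits — the largest
edit distance any hit with identity ≥ `T` can have — so hopeless
alignments are pruned early.

The package also ships the surrounding toolkit: an orthogonal fragment
library designer (homopolymer-free, Wallace-Tm matched, minimum pairwise
edit distance in both orientations), nanopore-style read simulators with
ground truth (uniform error rates, a positional high-error-start profile,
and fragment-free random reads), a FASTQ-quality error-profile extractor,
and evaluation of coverings against ground truth.

## Worked example

```
$ fragtiler design --seed 7 --out frags.fasta
INFO designed 22 fragments -> frags.fasta (validator: {'ok': True, 'longest_homopolymer': 1,
     'min_pairwise_edit': 4, 'max_tm_deviation': 4})

$ fragtiler simulate uniform --library frags.fasta --n-reads 200 --rate 0.05 \
      --seed 7 --fastq-out reads.fastq --truth-out truth.csv
INFO wrote 200 reads to reads.fastq

$ fragtiler cover reads.fastq frags.fasta --no-search-rc
INFO reads processed: 200; with >=1 placement: 200; mean percent covered: 99.0

$ fragtiler evaluate placements.csv truth.csv reads.fastq
reads evaluated:        200
fully covered reads:    187 (93.5%)
truth fragment slots:   2000
correct placements:     1985
incorrect placements:   9
missed fragments:       15
matching rule: id match with >= 50% overlap of the shorter interval
```

The 200 simulated reads each concatenate ten fragments drawn with
replacement from the designed 22-fragment pool and carry 5% uniform
per-base errors. At `T = 0.75` the greedy covering recovers 99% of read
bases and reconstructs 187/200 reads perfectly — a read counts as *fully
covered* only when every one of its ten true fragments is identified
correctly and no spurious fragment is placed. The placements CSV lists one
detected fragment per row with 0-based half-open coordinates:

```
# coordinates: 0-based, half-open
read_id,fragment_id,orientation,start,end,edit_distance,identity
sim5_00000,F20_1,+,0,19,2,0.9000
sim5_00000,F16_2,+,19,34,2,0.8750
```

and the coverage CSV reports the percent of each read covered by
fragments (`sim5_00000,158,157,99.4`).

The same pipeline is available as a library:

```python
import fragtiler as ft

lib = ft.design_library(seed=7)                       # 22 orthogonal fragments
read = ft.concatenate_fragments(lib, 10, seed=1)      # error-free ground truth
noisy = ft.apply_errors(read, 0.05, seed=2)           # 5% uniform errors
cov = ft.cover_read(noisy.sequence, lib, T=0.75, search_rc=False)
for p in cov.placements:
    print(p.fragment_id, p.start, p.end, p.edit_distance, round(p.identity, 3))
```

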