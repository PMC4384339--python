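# fmmap

Lossless inexact short-read mapping on an FM-index, built around a pruned
search-tree exploration. Given a maximum edit budget *e*, `fmmap` returns
**every** reference location where a read aligns with at most *e* edits —
mismatches, inserted reference bases and deleted read bases, at any read
position — making it suitable as a complete preprocessing/seeding stage in
front of a local-alignment mapper, and as a compact, fully tested reference
implementation of FM-index backward search with indel-aware backtracking.

## The method in brief

The index of the sentinel-terminated reference `X$` holds the BWT `B`,
the smaller-symbol counts `C(a)`, the occurrence table `O(a, i)` (count of
`a` in `B[0:i]`) and the sampled suffix array/inverse (`Scomp[k] = S[k·r]`,
`Rcomp[k] = R[k·r]`, reconstructed through
`Ψ⁻¹(i) = C(B[i]) + O(B[i], i+1)`); `O` is compressed into per-base bit
vectors of `w` bits plus running counts, queried with a masked popcount.
The same structures for the reversed text allow scanning a read in either
direction. Backward search narrows the SA interval `[k, l]` of the current
suffix; its size `res = l − k + 1` counts occurrences and can only shrink.

Inexact search explores a tree of edit alternatives with four lossless
bounds: dead intervals (`k > l`) are dropped; error branches open only where
`res' < res` (collapsing equivalent indel placements in repeats to one
canonical result); consecutive-edit pairs equivalent to a single cheaper
edit are refused; and a per-position lower bound `D` on the edits still
required — built from disjoint read windows that are not reference
substrings — prunes hopeless partial results. The production driver divides
the read into `e+1` segments and runs `e+1` steps, each exact-matching its
seed segment before allowing errors elsewhere (with one direction change),
which partitions the error placements exactly across steps. A single-pass
variant (`search_prototype`) and a brute-force dynamic-programming oracle
(`brute_force_map`) are included so every claim is testable; see
`docs/methods.md` for the full model description.

## Worked example

The reference `AGGAGC` indexes as suffix array `S = [6, 3, 0, 5, 2, 4, 1]`,
BWT `CG$GGAA`, `C = (0, 2, 3, 6)`:

```python
>>> import fmmap as fm
>>> idx = fm.build_index("AGGAGC")
>>> [idx.fwd.sa(k) for k in range(7)]
[6, 3, 0, 5, 2, 4, 1]
```

Exact backward search of `AG` narrows the interval to ranks `[1, 2]`, whose
suffix-array values are the two occurrence positions:

```python
>>> res = fm.bws(idx, "AG")
>>> (res.interval.k, res.interval.l), sorted(fm.locate(idx, res.interval, 2))
((1, 2), [0, 3])
```

The read `AGGATC` does not occur exactly, but one mismatch suffices. The
scan's occurrence count shrinks after `AG` and after `AGGA` — positions 2
and 4 are the only places worth branching — and the inexact search reports
the single mapping:

```python
>>> fm.detect_branch_points(idx, "AGGATC")
[2, 4]
>>> cfg = fm.SearchConfig(max_errors=1, segsize=3)
>>> for m in fm.search_complete(idx, "AGGATC", cfg):
...     print(m.position, m.strand, m.n_errors, m.edit_string)
0 + 1 4:M(G)
```

i.e. the read maps at reference position 0 with one mismatch at read
position 4, where the reference holds `G`. The brute-force oracle agrees:

```python
>>> sorted(fm.brute_force_map("AGGAGC", "AGGATC", 1))
[(0, 1)]
```

## Command line

```bash
fmmap simulate --ref-len 3000 --reads 50 --read-len 80 --mut-rate 0.01 \
               --seed 7 --out-prefix demo        # demo.fa, demo.fq, demo.truth.tsv
fmmap index --ref demo.fa --out demo.idx         # forward + reverse FM-index
fmmap map --index demo.idx --reads demo.fq --errors 2 --segsize 10 \
          --out demo.tsv --sam demo.sam
# [fmmap] INFO 49/50 reads mapped, 199 locations -> demo.tsv
fmmap verify --ref-len 1500 --reads 10 --read-len 50 --errors 2 --segsize 8 --seed 11
# identical to oracle on 10 reads (e=2)
```

The TSV columns are read id, record, 0-based position, strand, error count
and a compact edit list (`4:M(G)` = mismatch at read position 4 against
reference base G; `3:D` = read base 3 deleted; `5:I(A)` = reference base A
inserted before read position 5). `--sam` additionally writes a minimal SAM
dialect with CIGAR and `NM` tags. One read of the fifty stays unmapped: it
drew three mutations, beyond the `--errors 2` budget.

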