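"""A self-contained short-read matcher with the study aligner's contract.

Reads are placed against a set of reference *features* (genes, intergenic
regions, rRNA sequences) allowing at most ``max_mismatches`` substitutions
(default 2, the setting used for the original 36-bp libraries), ungapped,
on the forward strand.  A read whose best placement is achieved at more than
one location is a *repeat* and is discarded — or, for taxonomic use, all
equally-best features can be kept so ties can be resolved by lowest common
ancestor.

The matcher is k-mer seeded with the pigeonhole guarantee: a read is split
into ``max_mismatches + 1`` disjoint seeds of length *k*; any placement with
at most ``max_mismatches`` mismatches must match at least one seed exactly.
All candidate placements are then verified by direct comparison, so the
result is identical to a brute-force scan over every offset of every feature
(a property the test suite checks against exactly such a scan).

Implementation notes: features are concatenated into one uint8 code array
separated by sentinel padding longer than any read, so no placement can
straddle two features.  Reference k-mers are encoded base-8 (sentinels get a
digit no read base can produce) and kept in one sorted array; seed lookup is
a vectorised ``searchsorted``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

# read/reference alphabet codes; sentinel 7 never appears in an encoded read
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case
_SENTINEL = 7

STATUS_UNALIGNED = 0
STATUS_ALIGNED = 1
STATUS_REPEAT = 2


def encode_seq(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignmentResult:
    """Vectorised per-read placements.

    ``feature`` is the index into :attr:`FeatureIndex.names` (-1 when not
    aligned), ``offset`` the 0-based start within the feature, ``mismatches``
    the substitution count of the best placement (-1 when no placement was
    within the allowance), and ``status`` one of the ``STATUS_*`` codes.
    ``tie_features``, filled only when ``keep_ties=True``, maps a read index
    to the feature indices of all equally-best placements.
    """

    read_ids: list[str]
    feature: np.ndarray
    offset: np.ndarray
    mismatches: np.ndarray
    status: np.ndarray
    names: list[str]
    tie_features: dict[int, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.read_ids)

    @property
    def n_aligned(self) -> int:
        return int(np.count_nonzero(self.status == STATUS_ALIGNED))

    @property
    def n_repeat(self) -> int:
        return int(np.count_nonzero(self.status == STATUS_REPEAT))

    @property
    def n_unaligned(self) -> int:
        return int(np.count_nonzero(self.status == STATUS_UNALIGNED))


class FeatureIndex:
    """Seed index over a named set of reference sequences."""

    def __init__(self, names, seqs, k: int = 12, pad: int = 128):
        names = list(names)
        seqs = list(seqs)
        if not names:
            raise ValueError("empty reference")
        if len(names) != len(seqs):
            raise ValueError("names and seqs differ in length")
        if k < 4 or k > 20:
            raise ValueError("seed size k must be in [4, 20]")
        self.names = names
        self.k = k
        self.pad = pad
        self._lens = np.array([len(s) for s in seqs], dtype=np.int64)
        if np.any(self._lens == 0):
            raise ValueError("empty reference feature")
        starts = []
        parts = []
        cur = 0
        sep = np.full(pad, _SENTINEL, dtype=np.uint8)
        for s in seqs:
            starts.append(cur)
            parts.append(encode_seq(s))
            cur += len(s)
            parts.append(sep)
            cur += pad
        self._starts = np.array(starts, dtype=np.int64)
        self._starts_list = starts  # python list for bisect
        self._code = np.concatenate(parts)
        self._kmer_order, self._kmer_sorted = self._build_kmers()

    def _build_kmers(self):
        code = self._code.astype(np.int64)
        n = code.size - self.k + 1
        kmers = np.zeros(n, dtype=np.int64)
        for j in range(self.k):
            kmers *= 8
            kmers += code[j : j + n]
        order = np.argsort(kmers, kind="stable").astype(np.int64)
        return order, kmers[order]

    @property
    def lengths(self) -> np.ndarray:
        return self._lens

    def feature_length(self, name: str) -> int:
        return int(self._lens[self.names.index(name)])

    def _seed_codes(self, mat: np.ndarray, offsets) -> np.ndarray:
        m = mat.shape[0]
        out = np.zeros((m, len(offsets)), dtype=np.int64)
        for si, off in enumerate(offsets):
            acc = np.zeros(m, dtype=np.int64)
            for j in range(self.k):
                acc *= 8
                acc += mat[:, off + j]
            out[:, si] = acc
        return out

    def align(
        self,
        reads,
        max_mismatches: int = 2,
        keep_ties: bool = False,
    ) -> AlignmentResult:
        """Align ``reads`` (iterable of ``(id, seq)``) against the index."""
        reads = list(reads)
        ids = [r[0] for r in reads]
        n = len(reads)
        feature = np.full(n, -1, dtype=np.int64)
        offset = np.full(n, -1, dtype=np.int64)
        mism = np.full(n, -1, dtype=np.int64)
        status = np.zeros(n, dtype=np.int8)
        ties: dict[int, list[int]] = {}

        # group by read length so each group is one rectangular code matrix
        by_len: dict[int, list[int]] = {}
        for i, (_, seq) in enumerate(reads):
            by_len.setdefault(len(seq), []).append(i)

        nseeds = max_mismatches + 1
        max_feat = int(self._lens.max())
        code = self._code
        order = self._kmer_order
        sorted_k = self._kmer_sorted
        starts_list = self._starts_list
        lens = self._lens

        for length, idxs in by_len.items():
            if length > self.pad:
                raise ValueError(
                    f"read length {length} exceeds index padding {self.pad}"
                )
            if length > max_feat:
                raise ValueError("read longer than every reference feature")
            if nseeds * self.k > length:
                raise ValueError(
                    f"reads of length {length} too short for "
                    f"{nseeds} seeds of k={self.k}"
                )
            buf = "".join(reads[i][1] for i in idxs).encode("ascii")
            mat = _ENCODE[np.frombuffer(buf, dtype=np.uint8)].reshape(
                len(idxs), length
            )
            offsets = [s * self.k for s in range(nseeds)]
            seeds = self._seed_codes(mat, offsets)
            lo = np.searchsorted(sorted_k, seeds, side="left")
            hi = np.searchsorted(sorted_k, seeds, side="right")

            for row, i in enumerate(idxs):
                cand: set[int] = set()
                for si in range(nseeds):
                    a, b = lo[row, si], hi[row, si]
                    if a == b:
                        continue
                    off = offsets[si]
                    for p in order[a:b]:
                        cand.add(int(p) - off)
                if not cand:
                    continue
                rcode = mat[row]
                best = max_mismatches + 1
                best_hits: list[int] = []
                for st in cand:
                    if st < 0:
                        continue
                    fi = bisect_right(starts_list, st) - 1
                    if st + length > starts_list[fi] + int(lens[fi]):
                        continue
                    mm = int(
                        np.count_nonzero(code[st : st + length] != rcode)
                    )
                    if mm < best:
                        best = mm
                        best_hits = [st]
                    elif mm == best:
                        best_hits.append(st)
                if best > max_mismatches or not best_hits:
                    continue
                if len(best_hits) == 1:
                    st = best_hits[0]
                    fi = bisect_right(starts_list, st) - 1
                    feature[i] = fi
                    offset[i] = st - starts_list[fi]
                    mism[i] = best
                    status[i] = STATUS_ALIGNED
                else:
                    status[i] = STATUS_REPEAT
                    mism[i] = best
                    if keep_ties:
                        ties[i] = sorted(
                            {
                                bisect_right(starts_list, st) - 1
                                for st in best_hits
                            }
                        )
        return AlignmentResult(
            read_ids=ids,
            feature=feature,
            offset=offset,
            mismatches=mism,
            status=status,
            names=self.names,
            tie_features=ties,
        )


def align_reads(reads, reference, max_mismatches: int = 2, **kw) -> AlignmentResult:
    """Align ``(id, seq)`` pairs against ``reference``.

    ``reference`` may be a prebuilt :class:`FeatureIndex` or a mapping
    ``name -> sequence`` (an index is built on the fly).
    """
    if not isinstance(reference, FeatureIndex):
        reference = FeatureIndex(list(reference.keys()), list(reference.values()))
    return reference.align(reads, max_mismatches=max_mismatches, **kw)


def alignments_from_sam(path, names, with_reads: bool = False):
    """Load placements from a SAM/BAM file produced by an external aligner.

    Mapped primary records become aligned placements; unmapped records are
    kept as unaligned so read conservation still holds.  The reference names
    of the SAM header must be a subset of ``names`` (the feature universe).
    Mismatch counts are taken from the NM tag when present.  With
    ``with_reads=True`` also returns the ``(id, seq)`` pairs, parallel to
    the result, for downstream per-read haplotype assignment.
    """
    import pysam

    names = list(names)
    lookup = {n: i for i, n in enumerate(names)}
    ids, feats, offs, mms, stats, seqs = [], [], [], [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            ids.append(rec.query_name)
            seqs.append(rec.query_sequence or "")
            if rec.is_unmapped:
                feats.append(-1)
                offs.append(-1)
                mms.append(-1)
                stats.append(STATUS_UNALIGNED)
                continue
            try:
                fi = lookup[rec.reference_name]
            except KeyError:
                raise ValueError(
                    f"SAM reference {rec.reference_name!r} not in feature set"
                ) from None
            feats.append(fi)
            offs.append(rec.reference_start)
            mms.append(rec.get_tag("NM") if rec.has_tag("NM") else 0)
            stats.append(STATUS_ALIGNED)
    aln = AlignmentResult(
        read_ids=ids,
        feature=np.array(feats, dtype=np.int64),
        offset=np.array(offs, dtype=np.int64),
        mismatches=np.array(mms, dtype=np.int64),
        status=np.array(stats, dtype=np.int8),
        names=names,
    )
    if with_reads:
        return aln, list(zip(ids, seqs))
    return aln


def write_sam(aln: AlignmentResult, reads, lengths, path) -> None:
    """Write placements as SAM (mapped + unmapped records, NM tags).

    ``reads`` are the ``(id, seq)`` pairs in the order they were aligned and
    ``lengths`` the feature lengths parallel to ``aln.names``.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": n, "LN": int(ln)} for n, ln in zip(aln.names, lengths)
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, (rid, seq) in enumerate(reads):
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = rid
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if aln.status[i] == STATUS_ALIGNED:
                rec.flag = 0
                rec.reference_id = int(aln.feature[i])
                rec.reference_start = int(aln.offset[i])
                rec.mapping_quality = 255
                rec.cigarstring = f"{len(seq)}M"
                rec.set_tag("NM", int(aln.mismatches[i]))
            else:
                rec.flag = 4  # unaligned or discarded repeat
            sam.write(rec)
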