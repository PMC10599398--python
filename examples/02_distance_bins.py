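"""Distance-to-splice-site geometry: offsets, bins, isoform context.

The intronic offset counts the first intronic base next to an exon as 1,
so offsets 1-2 are the GT/AG dinucleotide itself.  Deep intronic variants
land in the 501-1000 and 1000+ bins.
"""

from intronbench import TranscriptModel, assign_bin, decompose_isoform_context, splice_distance

tx = TranscriptModel("TX1", "GENE", "chr1", "+", ((1001, 1200), (4201, 4400)))
print(f"transcript {tx.transcript_id}: intron {tx.introns[0]}\n")

for pos in (1201, 1202, 1210, 1500, 2600, 4200):
    ctx = splice_distance(pos, tx)
    print(
        f"pos {pos}: offset {ctx.intronic_offset:>4} from the {ctx.nearest_site_kind}"
        f" -> bin {assign_bin(ctx.intronic_offset)!r}"
    )

# A second isoform with an extra exon can make a "deep intronic" position
# exonic — the isoform-context decomposition catches this.
iso_b = TranscriptModel("TX2", "GENE", "chr1", "+", ((1001, 1200), (2501, 2600), (4201, 4400)))
cat = decompose_isoform_context(2550, [tx, iso_b], "TX1")
print(f"\npos 2550 is offset {splice_distance(2550, tx).intronic_offset} in TX1 "
      f"but classified {cat!r} against the gene's isoforms")
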