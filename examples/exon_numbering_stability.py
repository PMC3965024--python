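"""Stable exon numbering across transcripts, and its behaviour on extension.

Two transcripts share exons A and C while only one uses B: the union is
numbered 1..3 in genomic order and each transcript carries the projection.
Adding a transcript later — here with a novel exon between labels 1 and 2 —
never renumbers anything: the newcomer gets the next unused label (4).
"""

from lrgkit import ExonSpan, FixedTranscript, assign_exon_numbers, extend_numbering


def tx(name, *spans):
    exons = tuple(ExonSpan(s, e) for s, e in spans)
    return FixedTranscript(name, exons, "N" * sum(e.length for e in exons))


t1 = tx("t1", (101, 200), (501, 600))            # exons A, C
t2 = tx("t2", (101, 200), (301, 400), (501, 600))  # exons A, B, C
numbering = assign_exon_numbers([t1, t2])

print("initial numbering (union of t1 + t2, 5'->3'):")
for (start, end), label in sorted(numbering.labels.items(), key=lambda kv: kv[1]):
    print(f"  exon {label}: {start}-{end}")
for name, labels in numbering.per_transcript.items():
    print(f"  {name} uses labels {labels}")

t3 = tx("t3", (101, 200), (231, 260), (301, 400))  # novel exon between A and B
extended = extend_numbering(numbering, t3)

print("\nafter adding t3 (novel exon 231-260):")
for (start, end), label in sorted(extended.labels.items(), key=lambda kv: kv[1]):
    print(f"  exon {label}: {start}-{end}")
print(f"  t3 uses labels {extended.per_transcript['t3']}")
print("  -> existing labels 1-3 untouched; the new exon took label 4")
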