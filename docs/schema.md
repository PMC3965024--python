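# XML dialect

`lrgkit` stores each record as a single XML file. The dialect is a minimal,
self-describing rendering of the record's content tree; it is **not** the
official LRG schema (v1.8), though its element names are chosen so that a
reader familiar with that schema will recognise everything. Files carry a
`schema_version` attribute on the root so future revisions can be detected.

All coordinates are 1-based, fully closed. All sequences are uppercase;
lowercase input is case-folded on read.

## Layout

```xml
<lrg schema_version="0.1">
  <id>LRG_9001</id>
  <status>public</status>                  <!-- pending | public -->

  <fixed_annotation>
    <hgnc_symbol>COL1A1</hgnc_symbol>
    <source>requester free text</source>   <!-- zero or more -->
    <sequence>ACGT...</sequence>           <!-- LRG genomic sequence -->

    <transcript name="t1">                 <!-- names t1, t2, ... in order -->
      <exon start="5001" end="5229"/>      <!-- LRG-genomic spans, ascending -->
      ...
      <cdna>ACGT...</cdna>                 <!-- exon concatenation, no poly-A -->
      <coding_region start="36" end="566"/> <!-- cDNA coords, start..stop codon;
                                                 absent for non-coding -->
      <protein name="p1">MGPA...</protein> <!-- 1-letter; absent if non-coding -->
    </transcript>

    <exon_numbering>
      <exon start="5001" end="5229" label="1"/>   <!-- one per distinct span -->
      <transcript name="t1" labels="1,2,3"/>      <!-- projection per transcript -->
    </exon_numbering>
  </fixed_annotation>

  <updatable_annotation>
    <mapping assembly="GRCh38" other_name="chr17">
      <span lrg_start="1" lrg_end="8298" other_start="10694"
            other_end="18991" strand="1"/>        <!-- strand 1 or -1 -->
      <diff kind="mismatch" lrg_start="5" lrg_end="5" other_start="10698"
            other_end="10698" lrg_allele="A" other_allele="G"/>
      <!-- kinds: mismatch | lrg_insertion | assembly_insertion -->
    </mapping>

    <annotation_set source="NCBI">          <!-- NCBI|Ensembl|LSDB|community -->
      <gene symbol="COL1A1" start="5001" end="6298" partial="false">
        <synonym>OI4</synonym>
        <xref db="GeneID" id="1277"/>
        <transcript name="NM_000088"><exon start="5001" end="5229"/></transcript>
      </gene>
      <fixed_transcript_mark name="t1"/>    <!-- fixed transcript echoed here -->
    </annotation_set>

    <legacy_numbering name="lit1999" aa_offset="-23">
      <exon lrg_label="1" legacy_label="1A"/>
    </legacy_numbering>

    <note>free text (e.g. a supersession notice)</note>
  </updatable_annotation>
</lrg>
```

## Reading rules

* Mandatory elements: `<id>`, `<status>`, `<fixed_annotation>` with
  `<hgnc_symbol>`, `<sequence>` and `<exon_numbering>`. A missing mandatory
  element is a parse error naming the element; a non-numeric coordinate
  attribute is a parse error naming the attribute and value.
* Unrecognised children of `<updatable_annotation>` are preserved verbatim
  in an opaque extras store and re-emitted (after the known elements) on
  write, so richer files survive a read/write round trip. This is why the
  reader does not reject unknown elements.
* Writing is deterministic — stable element and attribute order — so
  identical records always serialise to identical bytes. `write_lrg` refuses
  a record with error-severity validation violations unless `force=True`.

## FASTA export

`export_fasta(record, selector)` emits one sequence per call: header
`>LRG_1` for `selector="genomic"`, `>LRG_1t1` / `>LRG_1p1` for transcript
cDNA / protein selectors, wrapped at 60 columns, uppercase.
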