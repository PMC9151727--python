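# External source tables (not redistributed)

The acceptance targets that reproduce published numbers are defined over
source tables that ship with the original publications, not with this
package. Drop transcriptions of them into this directory (or point
`CASBIND_EXTERNAL_DIR` elsewhere) and the red acceptance tests plus the
omitted keys in `scripts/acceptance.py` light up automatically.

## `crisproff_parameters.json`

A parameter file in the casbind JSON format (see
`src/casbind/data/nn_params_v1.json` for the schema) transcribed from the
CRISPRoff pipeline distribution (v1.1.2, rth.dk/resources/crispr/crisproff):
the fitted 19-element positional weight array (`CRISPR_20nt_5p_3p`) and the
full RNA-DNA/DNA-DNA/RNA-RNA stacking tables, including mismatch and bulge
steps. The packaged default file carries literature Watson-Crick tables with
**uniform weights** and is not a substitute when reproducing published
energy values such as the -66.85 kcal/mol worked example.

## `supplementary_data3.tsv`

The 4-guide (PAX5, BMP3, ADRA2C, CHRNB2) HEK293T PAM-context efficiency
table (Supplementary Data 3 of the article). Tab-separated with columns:

    gRNA_id   pam_context   treatment   indel_frequency   [day]   [barcode]

`treatment` is `Dox+` or `Dox-`; `indel_frequency` is in percent. If `day`
and `barcode` columns are present, replicates are averaged on load (days
first, then barcodes).

## `lin2014_guides.tsv`

The four guides of the single-deletion bulge dataset (Lin et al. 2014,
retrieved from that publication's supplement). Columns:

    id   spacer   gc_percent
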