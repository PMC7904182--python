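{
  "schema_version": 1,
  "comment": "Maps workbook sheet-name patterns (case-insensitive regex, searched) to figure keys. Unmatched sheets are kept raw under their own name.",
  "patterns": {
    "fig2e": ["fig\\.?\\s*2\\s*e", "2e"],
    "s1figd": ["s1\\s*fig\\.?\\s*d", "s1d"],
    "fig3a": ["fig\\.?\\s*3\\s*a"],
    "fig3c": ["fig\\.?\\s*3\\s*c"],
    "fig5c": ["fig\\.?\\s*5\\s*c"],
    "fig5f": ["fig\\.?\\s*5\\s*f"],
    "fig6c": ["fig\\.?\\s*6\\s*c"],
    "fig7c": ["fig\\.?\\s*7\\s*c"],
    "fig9b": ["fig\\.?\\s*9\\s*b"],
    "s3figc": ["s3\\s*fig\\.?\\s*c", "s3c"],
    "s3figab": ["s3\\s*fig\\.?\\s*a", "s3\\s*fig\\.?\\s*b"]
  }
}
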