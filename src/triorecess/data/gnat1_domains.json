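{
  "protein": "GNAT1",
  "protein_length": 350,
  "sites": [
    {"name": "Gtbg_1_23", "family": "Gtbg", "start": 1, "end": 23},
    {"name": "NLS_21_52", "family": "NLS", "start": 21, "end": 52},
    {"name": "Mg_43", "family": "Mg", "start": 43, "end": 43},
    {"name": "Mg_177", "family": "Mg", "start": 177, "end": 177},
    {"name": "GTP_36_43", "family": "GTP", "start": 36, "end": 43},
    {"name": "GTP_171_177", "family": "GTP", "start": 171, "end": 177},
    {"name": "GTP_196_200", "family": "GTP", "start": 196, "end": 200},
    {"name": "GTP_265_268", "family": "GTP", "start": 265, "end": 268},
    {"name": "GTP_321_323", "family": "GTP", "start": 321, "end": 323},
    {"name": "PDE6g_306_310", "family": "PDE6g", "start": 306, "end": 310},
    {"name": "RHO_311_328", "family": "RHO", "start": 311, "end": 328},
    {"name": "RHO_340_350", "family": "RHO", "start": 340, "end": 350}
  ]
}
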