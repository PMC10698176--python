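{
 "table1_studies.csv": "d246f303c73c1aa3fd3b60150ace6f2016e8014c7c64c240f28f3a2df7c773f6",
 "table5_status.csv": "889d9dbf288e6c5411b991d1c5ae675307a16cb8b349c26835004868aaf646a3",
 "table6_scores.csv": "86cf3881808ee9d1640ca38c9dd6108bd4dfb04b10a7c05f473d43ebe8fa9655"
}
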