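# SHA-256 integrity manifest for the shipped study tables.
file,sha256
clinical_studies.csv,e9edfa17ad7d12ad869c31ba74aa565fae33ae75be41c9ce1240da115121b027
ddi_ratios.csv,971dde316a9f8e9f79c303bf248584039ad5e1d95ecf15a2ed4f98ce8b95289a
ddi_summary.csv,f339641c0f89f281ae5ad3347e5795ac76dcc13aa62089b6dddc09e5dc354783
pk_footers.csv,572eef4e4fc80920c96ec190c922f8b0e2596656b3bf1d4bfb801959c3b2fa50
pk_observed_iv.csv,dcadd3a81f072d383e1bf6f2c8ecc469f13abce25a433c124798c54d0ad5e47d
pk_observed_oral.csv,ec6e757d882f37742ddb259c515ef65db90bcdbe024c4f8078e832432aea7811
scenario_settings.csv,ab6b9832679a2d589d8414d17e711b83d2746f5b58da94c7353187789d338b60
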