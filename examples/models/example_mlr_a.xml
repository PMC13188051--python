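<?xml version='1.0' encoding='utf-8'?>
<qsar_model type="mlr" version="1">
  <metadata id="example_mlr_a" endpoint="synthetic pLC50" units="-log10(mol/L)" group="Examples" subgroup="Synthetic endpoint A">
    <citation>synthetic example model A</citation>
  </metadata>
  <descriptors>
    <descriptor name="d1" source="supplied" />
    <descriptor name="d2" source="supplied" />
  </descriptors>
  <training>
    <chemical id="t1">
      <value d="d1">-1.4238250364546312</value>
      <value d="d2">1.2637284581291104</value>
      <endpoint>1.8644406711396333</endpoint>
    </chemical>
    <chemical id="t2">
      <value d="d1">-0.87066173795908575</value>
      <value d="d2">-0.25917323493439759</value>
      <endpoint>-1.2941012146680269</endpoint>
    </chemical>
    <chemical id="t3">
      <value d="d1">-0.075343307010520971</value>
      <value d="d2">-0.74088465208560905</value>
      <endpoint>-2.0451411065210667</endpoint>
    </chemical>
    <chemical id="t4">
      <value d="d1">-1.3677927017829434</value>
      <value d="d2">0.64889280219303991</value>
      <endpoint>0.17024920766481591</endpoint>
    </chemical>
    <chemical id="t5">
      <value d="d1">0.36105811305489499</value>
      <value d="d2">-1.9528630630121899</value>
      <endpoint>-3.2741029967686144</endpoint>
    </chemical>
    <chemical id="t6">
      <value d="d1">2.3474096543788519</value>
      <value d="d2">0.9684969057519236</value>
      <endpoint>9.909389739197394</endpoint>
    </chemical>
    <chemical id="t7">
      <value d="d1">-0.75938718042450659</value>
      <value d="d2">0.90219827421225174</value>
      <endpoint>2.5765011336931258</endpoint>
    </chemical>
    <chemical id="t8">
      <value d="d1">-0.46695317332055025</value>
      <value d="d2">-0.060689518737027978</value>
      <endpoint>0.29834169493148593</endpoint>
    </chemical>
    <chemical id="t9">
      <value d="d1">0.78884434451920082</value>
      <value d="d2">-1.2566681331396765</value>
      <endpoint>-1.6718098668896333</endpoint>
    </chemical>
    <chemical id="t10">
      <value d="d1">0.57585751439592869</value>
      <value d="d2">1.3989789947237192</value>
      <endpoint>5.7439578694758566</endpoint>
    </chemical>
    <chemical id="t11">
      <value d="d1">1.3222980607327857</value>
      <value d="d2">-0.29969851529910546</value>
      <endpoint>2.0393545688311958</endpoint>
    </chemical>
    <chemical id="t12">
      <value d="d1">0.90291934142505981</value>
      <value d="d2">-1.6215827341822058</value>
      <endpoint>-1.7881361047439712</endpoint>
    </chemical>
  </training>
  <coefficients intercept="1.0638702523210235">
    <coef d="d1">2.0998747069769585</coef>
    <coef d="d2">3.0117205773220812</coef>
  </coefficients>
</qsar_model>
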