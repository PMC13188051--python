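<?xml version='1.0' encoding='utf-8'?>
<qsar_model type="mlr" version="1">
  <metadata id="example_mlr_b" endpoint="synthetic pLC50" units="-log10(mol/L)" group="Examples" subgroup="Synthetic endpoint A">
    <citation>synthetic example model B</citation>
  </metadata>
  <descriptors>
    <descriptor name="d1" source="supplied" />
    <descriptor name="d2" source="supplied" />
  </descriptors>
  <training>
    <chemical id="t1">
      <value d="d1">-0.90388899979428272</value>
      <value d="d2">0.15713145715131374</value>
      <endpoint>-1.457753625260618</endpoint>
    </chemical>
    <chemical id="t2">
      <value d="d1">0.8976119866651816</value>
      <value d="d2">-0.76219554144624468</value>
      <endpoint>0.2719577315924388</endpoint>
    </chemical>
    <chemical id="t3">
      <value d="d1">-0.17625556327648054</value>
      <value d="d2">0.053031720890262375</value>
      <endpoint>0.8448636757053507</endpoint>
    </chemical>
    <chemical id="t4">
      <value d="d1">-1.6284402816157311</value>
      <value d="d2">-0.17753333139257513</value>
      <endpoint>-2.2365278036861462</endpoint>
    </chemical>
    <chemical id="t5">
      <value d="d1">1.9636035221338848</value>
      <value d="d2">1.7812547753881378</value>
      <endpoint>8.9458577356292022</endpoint>
    </chemical>
    <chemical id="t6">
      <value d="d1">-0.87971984127872804</value>
      <value d="d2">-1.6984791280489404</value>
      <endpoint>-4.4675090423157693</endpoint>
    </chemical>
    <chemical id="t7">
      <value d="d1">-1.8189109094780658</value>
      <value d="d2">0.11895452694343503</value>
      <endpoint>-2.0698093383539291</endpoint>
    </chemical>
    <chemical id="t8">
      <value d="d1">-0.44409513128645739</value>
      <value d="d2">0.76911420936707653</value>
      <endpoint>4.096156050690972</endpoint>
    </chemical>
    <chemical id="t9">
      <value d="d1">-0.034337779509927752</value>
      <value d="d2">0.39252775562305786</value>
      <endpoint>2.3855063964502241</endpoint>
    </chemical>
    <chemical id="t10">
      <value d="d1">0.75891810734727938</value>
      <value d="d2">-0.070459673786287327</value>
      <endpoint>3.484984210350301</endpoint>
    </chemical>
    <chemical id="t11">
      <value d="d1">1.049847747582267</value>
      <value d="d2">1.0296707223968031</value>
      <endpoint>6.588016754726989</endpoint>
    </chemical>
    <chemical id="t12">
      <value d="d1">-0.42005532607978374</value>
      <value d="d2">0.78626627388320181</value>
      <endpoint>1.3617719812178959</endpoint>
    </chemical>
    <chemical id="t13">
      <value d="d1">0.96124928617191885</value>
      <value d="d2">-2.1450347566570995</value>
      <endpoint>-3.7014779973660552</endpoint>
    </chemical>
    <chemical id="t14">
      <value d="d1">-0.76576813111972486</value>
      <value d="d2">0.62241054713409327</value>
      <endpoint>2.1452973532235315</endpoint>
    </chemical>
    <chemical id="t15">
      <value d="d1">0.9791894809182291</value>
      <value d="d2">0.92941486588493516</value>
      <endpoint>5.5570180393014992</endpoint>
    </chemical>
  </training>
  <coefficients intercept="1.170616222403742">
    <coef d="d1">1.7849540862288269</coef>
    <coef d="d2">2.8061905332595098</coef>
  </coefficients>
</qsar_model>
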