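<?xml version="1.0" encoding="UTF-8"?>
<!--
  Annotated sample of the supported annotation XML dialect (synthetic
  content, not taken from any real scan).

  Structure:
    LidcReadMessage            document root (a default namespace is
                               accepted and ignored)
      readingSession           one per reader; reader identity is never
                               encoded, only the session ordinal
        unblindedReadNodule    one per annotated finding in the session
          noduleID             the annotation identifier (string)
          characteristics      optional; up to nine ratings, integer text:
                               subtlety 1-5, internalStructure 1-4,
                               calcification 1-6, sphericity 1-5,
                               margin 1-5, lobulation 1-5, spiculation 1-5,
                               texture 1-5, malignancy 1-5
          roi                  one per slice contour
            imageZposition     patient-space z of the slice in mm
            imageSOP_UID       SOPInstanceUID of the CT slice drawn on
            inclusion          TRUE = included region, FALSE = excluded
            edgeMap            one per contour point, 0-based integer
              xCoord           pixel column
              yCoord           pixel row
                               Contour points trace the pixels just OUTSIDE
                               the region; a single edgeMap marks a
                               center-of-mass only (not volumetric).
-->
<LidcReadMessage>
  <ResponseHeader>
    <Version>1.0</Version>
  </ResponseHeader>
  <readingSession>
    <unblindedReadNodule>
      <noduleID>101</noduleID>
      <characteristics>
        <subtlety>4</subtlety>
        <internalStructure>1</internalStructure>
        <calcification>6</calcification>
        <sphericity>5</sphericity>
        <margin>4</margin>
        <lobulation>2</lobulation>
        <spiculation>1</spiculation>
        <texture>5</texture>
        <malignancy>3</malignancy>
      </characteristics>
      <roi>
        <imageZposition>-112.5000</imageZposition>
        <imageSOP_UID>1.2.826.0.1.3680043.8.498.1.1001.1</imageSOP_UID>
        <inclusion>TRUE</inclusion>
        <edgeMap><xCoord>10</xCoord><yCoord>10</yCoord></edgeMap>
        <edgeMap><xCoord>11</xCoord><yCoord>10</yCoord></edgeMap>
        <edgeMap><xCoord>12</xCoord><yCoord>10</yCoord></edgeMap>
        <edgeMap><xCoord>12</xCoord><yCoord>11</yCoord></edgeMap>
        <edgeMap><xCoord>12</xCoord><yCoord>12</yCoord></edgeMap>
        <edgeMap><xCoord>11</xCoord><yCoord>12</yCoord></edgeMap>
        <edgeMap><xCoord>10</xCoord><yCoord>12</yCoord></edgeMap>
        <edgeMap><xCoord>10</xCoord><yCoord>11</yCoord></edgeMap>
      </roi>
    </unblindedReadNodule>
  </readingSession>
  <readingSession>
    <unblindedReadNodule>
      <noduleID>201</noduleID>
      <roi>
        <imageZposition>-110.0000</imageZposition>
        <imageSOP_UID>1.2.826.0.1.3680043.8.498.1.1001.2</imageSOP_UID>
        <inclusion>TRUE</inclusion>
        <edgeMap><xCoord>40</xCoord><yCoord>40</yCoord></edgeMap>
      </roi>
    </unblindedReadNodule>
  </readingSession>
</LidcReadMessage>
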